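"""The model's building blocks: a leaky integrator and an adaptive photoreceptor.

Steps a LIN and an adaptive-LIN through a luminance step and prints the
landmarks of their responses.  The LIN relaxes exponentially toward its
input; the adaptive unit responds only to the change, with a transient that
peaks within ~10 ms and decays back to zero as the adaptation current
catches up — that decay is what makes the downstream motion detectors
sensitive to moving edges rather than standing patterns.
"""

from beeav import AdaptiveLINState, LINState, step_adaptive_lin, step_lin

DT = 0.1  # ms

lin = LINState(a=0.0, tau=5.0)
for i in range(int(25 / DT)):
    lin = step_lin(lin, 1.0, DT)
    if (i + 1) % int(5 / DT) == 0:
        print(f"LIN(tau=5ms) at t={(i+1)*DT:4.1f} ms: a = {lin.a:.4f}")

print()
pr = AdaptiveLINState()  # tau_PR = 8 ms, tau_alpha = 15 ms
peak, t_peak = 0.0, 0.0
for i in range(int(120 / DT)):
    pr = step_adaptive_lin(pr, 1.0, DT)  # luminance step 0 -> 1 at t = 0
    if pr.a_pr > peak:
        peak, t_peak = pr.a_pr, (i + 1) * DT
print(f"adaptive unit: transient peaks at {peak:.3f} after {t_peak:.1f} ms, "
      f"then decays to {pr.a_pr:.4f} by t = 120 ms (adaptation alpha = {pr.alpha:.3f})")
print("-> under constant light the photoreceptor stage reports nothing; "
      "only luminance changes propagate to the motion detectors.")
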