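"""Closed-loop corridor flight and the visual odometry metric.

The three smoothed array outputs S_L, S_R and S_C feed a lateral / height /
speed controller in the style of Serres et al.'s dual optic-flow regulator.
Once per 10 ms control interval the pose is nudged by

    dX = sgn(S_L, S_R) * (max(S_L, S_R) - T_X) / 2.4     (cm, toward the
                                                          weaker-flow side)
    dZ = (S_C - T_Z) / 18.0                              (cm)
    dV = -(S_L + S_R - T_V) / 2.4                        (cm/s)

with sgn(A, B) = +1 for A > B, -1 for A < B and 0 on a tie.  Between control
updates the bee advances along the corridor at its current speed; the whole
loop is deterministic.

The visual odometer is the summed lateral detector output per cm travelled,
D_E = sum_t(S_L + S_R) / D, accumulated at control resolution over a trial.
For a spatial-frequency-invariant detector D_E is constant across wall
patterns, which is what lets bees gauge distance from integrated optic flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigurationError
from .systems import FullSystem
from .world import BeePose, CorridorRenderer, CorridorWorld

__all__ = ["ControllerParams", "Trajectory", "controller_step", "run_trial",
           "odometry_metric"]


@dataclass(frozen=True)
class ControllerParams:
    """Setpoints and scalings of the three flight controllers.

    Setpoints are in detector-output units (dimensionless ratios).  T_V is
    twice the lateral setpoint, so cruising speed settles where the two
    lateral flows sum to twice the per-side target.
    """

    t_x: float = 1.0
    t_z: float = 0.5
    t_v: float = 2.0
    div_x: float = 2.4
    div_z: float = 18.0
    div_v: float = 2.4
    #: interval between control updates, ms.  The printed deltas are per
    #: control step, so this sets the loop gains: 2 ms makes the slowest loop
    #: (speed, via the S(v) slope) settle within ~1 s, well inside a 5 s
    #: trial, while keeping commanded lateral speeds below forward speed.
    control_dt: float = 2.0

    def __post_init__(self) -> None:
        if min(self.div_x, self.div_z, self.div_v) <= 0:
            raise ConfigurationError("controller divisors must be > 0")
        if self.control_dt <= 0:
            raise ConfigurationError("control_dt must be > 0")


def _sgn(a: float, b: float) -> float:
    if a > b:
        return 1.0
    if a < b:
        return -1.0
    return 0.0


def controller_step(s_l: float, s_r: float, s_c: float,
                    p: ControllerParams) -> tuple[float, float, float]:
    """One control update: returns (dX cm, dZ cm, dV cm/s)."""
    dx = _sgn(s_l, s_r) * (max(s_l, s_r) - p.t_x) / p.div_x
    dz = (s_c - p.t_z) / p.div_z
    dv = -(s_l + s_r - p.t_v) / p.div_v
    return dx, dz, dv


@dataclass
class Trajectory:
    """Closed-loop flight record at control resolution."""

    t: np.ndarray  # s
    x: np.ndarray  # cm, lateral (0 = midline)
    z: np.ndarray  # cm, height
    y: np.ndarray  # cm, along corridor
    v: np.ndarray  # cm/s
    s_l: np.ndarray = field(repr=False, default=None)
    s_r: np.ndarray = field(repr=False, default=None)
    s_c: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.x, "z": self.z, "y": self.y,
                             "v": self.v, "S_L": self.s_l, "S_R": self.s_r,
                             "S_C": self.s_c})

    def mean_lateral_offset(self, window_s: float = 2.0) -> float:
        """Mean lateral position over the final ``window_s`` seconds."""
        mask = self.t > self.t[-1] - window_s
        return float(np.mean(self.x[mask]))


def run_trial(world: CorridorWorld, system: FullSystem,
              controller: ControllerParams | None = None,
              duration: float = 5.0, start: BeePose | None = None,
              settle: float = 0.5) -> Trajectory:
    """Fly the full system down the corridor for ``duration`` seconds.

    Every simulation step (system.dt, 0.1 ms by default) the frame is
    rendered at the current pose, the three detector arrays advance, and the
    bee moves forward by v*dt; every ``controller.control_dt`` the pose and
    speed are updated from the detector outputs.  Lateral position is kept
    0.5 cm clear of the walls, height 0.5 cm clear of floor and ceiling, and
    speed is floored at zero.

    ``settle`` is a sensory warm-up (seconds) flown straight at the start
    pose's speed before t = 0 with the controller disengaged, so that the
    smoothing and adaptation filters hold their steady flight values when
    control begins — the model bee enters the measured corridor section
    already flying, rather than with every neuron at zero.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be > 0")
    controller = controller or ControllerParams()
    pose = BeePose(**vars(start)) if start is not None else BeePose()
    renderer = CorridorRenderer(world)
    dt_s = system.dt / 1000.0
    n_steps = int(round(duration * 1000.0 / system.dt))
    for _ in range(int(round(settle * 1000.0 / system.dt))):
        system.step(renderer.render(pose))
        pose.y += pose.v * dt_s
    every = int(round(controller.control_dt / system.dt))
    if every < 1 or abs(every * system.dt - controller.control_dt) > 1e-9:
        raise ConfigurationError("control_dt must be a multiple of the simulation dt")

    x_lim = world.width / 2.0 - 0.5
    z_lo, z_hi = 0.5, world.height - 0.5
    n_rec = n_steps // every
    rec = {k: np.empty(n_rec) for k in ("t", "x", "z", "y", "v", "s_l", "s_r", "s_c")}
    i_rec = 0
    s_l = s_r = s_c = 0.0
    for i in range(n_steps):
        frame = renderer.render(pose)
        s_l, s_r, s_c = system.step(frame)
        if not (np.isfinite(s_l) and np.isfinite(s_r) and np.isfinite(s_c)):
            raise ConfigurationError(
                f"non-finite detector output at t={i * dt_s:.4f}s "
                f"(S_L={s_l}, S_R={s_r}, S_C={s_c})")
        pose.y += pose.v * dt_s
        if (i + 1) % every == 0:
            dx, dz, dv = controller_step(s_l, s_r, s_c, controller)
            pose.x = float(np.clip(pose.x + dx, -x_lim, x_lim))
            pose.z = float(np.clip(pose.z + dz, z_lo, z_hi))
            pose.v = max(0.0, pose.v + dv)
            for k, val in zip(("t", "x", "z", "y", "v", "s_l", "s_r", "s_c"),
                              ((i + 1) * dt_s, pose.x, pose.z, pose.y, pose.v,
                               s_l, s_r, s_c)):
                rec[k][i_rec] = val
            i_rec += 1
    return Trajectory(**rec)


def odometry_metric(traj: Trajectory) -> float:
    """Summed detector output per unit distance, D_E = sum_t(S_L + S_R) / D.

    D is the along-corridor distance covered by the trajectory, cm.
    """
    d = float(traj.y[-1] - traj.y[0])
    if d <= 0:
        raise ConfigurationError("total distance must be > 0 for odometry")
    return float(np.sum(traj.s_l + traj.s_r) / d)
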