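"""Closed-loop behavioural experiment drivers.

Three virtual corridor experiments probe the detector through behaviour:

* **Centering deviations vs spatial frequency** — one (sinusoidal) wall held
  at a constant frequency, the other varied; an imperfect AV detector is
  displaced toward the wall whose pattern it under-reads, and real bees
  deviate toward the higher-frequency wall by up to ~3 cm in a 20 cm
  corridor.  Run for the regressive scalings F in {0.0, 0.25, 0.5}.
* **Square vs sine deviations** — the eight combinations of waveform and
  frequency {0.15, 0.6} c/deg on the two walls, probing wide-band versus
  narrow-band responses.
* **Visual odometry** — identical square-wave walls; the summed lateral
  detector output per cm travelled (D_E) should be constant across wall
  frequencies if the detector is a usable odometer.

All frequencies in the public interfaces are *bee-scale* cycles/deg; the
drivers convert to the model's fivefold-coarser scale internally.  Every
trial follows the standard protocol: 5 s of controlled flight, entered at
3 cm lateral offset (both sides, averaged), 6 cm height and 40 cm/s, with
the final position taken as the mean over the last two seconds.  The model
is deterministic, so repetitions differ only through the starting pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detector import AVDUParams
from .flight import ControllerParams, Trajectory, odometry_metric, run_trial
from .systems import build_full_system
from .world import BeePose, CorridorWorld, SubregionLayout, SurfaceGrating, \
    bee_to_model_frequency

__all__ = ["TrialProtocol", "centering_trial", "experiment_1a", "experiment_1b",
           "experiment_odometry"]

#: bee-scale variable-wall frequency grid of the frequency-deviation experiment
DEFAULT_VARIABLE_FREQS = (0.05, 0.1, 0.15, 0.2, 0.3, 0.45, 0.6, 0.8)


@dataclass(frozen=True)
class TrialProtocol:
    """The shared trial recipe for all corridor experiments."""

    duration: float = 5.0  # s
    average_window: float = 2.0  # s, final-position averaging
    start_offset: float = 3.0  # cm, each side of the midline
    start_height: float = 6.0  # cm
    start_speed: float = 40.0  # cm/s
    settle: float = 0.5  # s of sensory warm-up before control engages

    def starts(self) -> tuple[BeePose, BeePose]:
        return (BeePose(x=+self.start_offset, z=self.start_height, v=self.start_speed),
                BeePose(x=-self.start_offset, z=self.start_height, v=self.start_speed))


def _make_world(left: SurfaceGrating, right: SurfaceGrating) -> CorridorWorld:
    return CorridorWorld(left_wall=left, right_wall=right)


def _wall(freq_bee: float, waveform: str) -> SurfaceGrating:
    return SurfaceGrating(waveform=waveform, frequency=bee_to_model_frequency(freq_bee))


def centering_trial(params: AVDUParams, left: SurfaceGrating, right: SurfaceGrating,
                    protocol: TrialProtocol = TrialProtocol(),
                    controller: ControllerParams | None = None,
                    layout: SubregionLayout | None = None,
                    ) -> tuple[float, list[float], list[Trajectory]]:
    """One experimental condition: a mirrored pair of runs.

    Returns (mean offset, per-run offsets, trajectories); offsets are in cm,
    positive toward the right wall.
    """
    world = _make_world(left, right)
    offsets, trajs = [], []
    for start in protocol.starts():
        system = build_full_system(params, layout)
        traj = run_trial(world, system, controller, protocol.duration, start,
                         settle=protocol.settle)
        offsets.append(traj.mean_lateral_offset(protocol.average_window))
        trajs.append(traj)
    return float(np.mean(offsets)), offsets, trajs


def experiment_1a(f_values=(0.0, 0.25, 0.5), constant_freqs=(0.15, 0.6),
                  variable_freqs=DEFAULT_VARIABLE_FREQS,
                  params: AVDUParams = AVDUParams(),
                  protocol: TrialProtocol = TrialProtocol(),
                  controller: ControllerParams | None = None) -> pd.DataFrame:
    """Deviation vs variable-wall spatial frequency, sinusoidal walls.

    The constant wall is the left wall; positive offsets are toward the
    variable (right) wall, so agreement with the bee data means offsets of
    the same sign as (variable - constant) frequency.  Returns one row per
    condition with the per-start offsets and their spread.
    """
    rows = []
    for F in f_values:
        p = params.with_(F=F)
        for fc in constant_freqs:
            for fv in variable_freqs:
                mean, offs, _ = centering_trial(
                    p, _wall(fc, "sine"), _wall(fv, "sine"), protocol, controller)
                rows.append({
                    "F": F, "constant_freq": fc, "variable_freq": fv,
                    "offset": mean, "offset_run1": offs[0], "offset_run2": offs[1],
                    "pair_range": abs(offs[0] - offs[1]),
                    "toward_higher_freq": (mean * (fv - fc) > 0) if fv != fc else None,
                })
    return pd.DataFrame(rows)


def experiment_1b(freqs=(0.15, 0.6), params: AVDUParams = AVDUParams(),
                  protocol: TrialProtocol = TrialProtocol(),
                  controller: ControllerParams | None = None) -> pd.DataFrame:
    """Square/sine wall combinations at two spatial frequencies.

    The left wall is always sinusoidal (narrow band); the right wall takes
    either waveform, giving the eight combinations of right-wall type and
    the two frequencies on each wall.  The 0.6 c/deg square-wave cells are
    flagged: at that frequency the square pattern's harmonics are beyond the
    model eye's resolution, the condition the bee data is known to
    contradict.
    """
    rows = []
    for fa in freqs:
        for waveform_b in ("sine", "square"):
            for fb in freqs:
                mean, offs, _ = centering_trial(
                    params, _wall(fa, "sine"), _wall(fb, waveform_b),
                    protocol, controller)
                rows.append({
                    "left_freq": fa, "right_type": waveform_b, "right_freq": fb,
                    "offset": mean, "offset_run1": offs[0], "offset_run2": offs[1],
                    "known_exception": waveform_b == "square" and fb == 0.6,
                })
    return pd.DataFrame(rows)


def experiment_odometry(freqs=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8),
                        params: AVDUParams = AVDUParams(),
                        protocol: TrialProtocol = TrialProtocol(),
                        controller: ControllerParams | None = None) -> pd.DataFrame:
    """D_E per wall frequency: identical square-wave patterns on both walls.

    Trials start on the midline (the walls are identical, so lateral
    symmetry holds) and D_E accumulates S_L + S_R at control resolution over
    the full trial, divided by the distance flown.
    """
    rows = []
    for f in freqs:
        wall = _wall(f, "square")
        world = _make_world(wall, wall)
        system = build_full_system(params)
        start = BeePose(x=0.0, z=protocol.start_height, v=protocol.start_speed)
        traj = run_trial(world, system, controller, protocol.duration, start,
                         settle=protocol.settle)
        rows.append({
            "freq": f, "D_E": odometry_metric(traj),
            "distance": float(traj.y[-1] - traj.y[0]),
            "final_speed": float(traj.v[-1]),
        })
    return pd.DataFrame(rows)
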