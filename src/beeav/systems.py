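"""Wiring detector arrays to the two sampling geometries.

The *test system* places one AVDU between every adjacent pair of locations
along the rows of the 100 x 2 grid (99 per row, 198 in all), all feeding a
single summation/ratio stage.  The *full system* covers three subregions of
the 32 x 32 ommatidial frame — left, right and ventral-centre — each with
its own summation/ratio stage producing the outputs S_L, S_R and S_C that
drive the flight controller.  All subregions prefer motion away from the
centre of the frame, which is the direction of optic flow under forward
flight.
"""

from __future__ import annotations

import numpy as np

from .core import ConfigurationError
from .detector import DT_MS, ArraySums, AVDUParams, DetectorArray
from .world import (
    BeePose,
    CorridorRenderer,
    CorridorWorld,
    Grating,
    SubregionLayout,
    TestArrayGeometry,
    sample_test_array,
)

__all__ = ["TestSystem", "FullSystem", "build_test_system", "build_full_system"]


class TestSystem:
    """Open-loop measurement rig: a detector array over the 100 x 2 grid."""

    def __init__(self, params: AVDUParams, geom: TestArrayGeometry | None = None,
                 dt: float = DT_MS):
        self.geom = geom or TestArrayGeometry()
        self.array = DetectorArray(self.geom.n_rows, self.geom.n_cols, params, dt)
        self.dt = dt

    @property
    def n_avdus(self) -> int:
        return self.array.n_detectors

    def step(self, g: Grating, t: float) -> ArraySums:
        return self.array.step(sample_test_array(self.geom, g, t))


def build_test_system(params: AVDUParams, geom: TestArrayGeometry | None = None,
                      dt: float = DT_MS) -> TestSystem:
    """Instantiate the test system, checking the detector count."""
    system = TestSystem(params, geom, dt)
    expected = system.geom.n_avdus
    if system.n_avdus != expected:
        raise ConfigurationError(
            f"built {system.n_avdus} AVDUs, geometry implies {expected}")
    return system


def _span(bounds: tuple[int, int]) -> slice:
    """1-based inclusive (lo, hi) -> 0-based slice."""
    lo, hi = bounds
    return slice(lo - 1, hi)


class FullSystem:
    """Three detector arrays over subregions of the ommatidial frame.

    Frame convention: ``frame[row, col]`` with row 0 the bottom (ventral)
    row, matching the layout's 1-based row 1.  Each array's input chains are
    ordered so that increasing index runs along the subregion's preferred
    direction (leftward for the left subregion, rightward for the right,
    downward for the centre).
    """

    def __init__(self, params: AVDUParams, layout: SubregionLayout | None = None,
                 dt: float = DT_MS):
        self.params = params
        self.layout = layout or SubregionLayout()
        self.dt = dt
        lay = self.layout

        def make(rows, cols, along_cols: bool) -> DetectorArray | None:
            n_rows = rows[1] - rows[0] + 1
            n_cols = cols[1] - cols[0] + 1
            if n_rows <= 0 or n_cols <= 0:
                return None
            if along_cols:
                return DetectorArray(n_cols, n_rows, params, dt)
            return DetectorArray(n_rows, n_cols, params, dt)

        self.left = make(lay.left_rows, lay.left_cols, along_cols=False)
        self.right = make(lay.right_rows, lay.right_cols, along_cols=False)
        self.centre = make(lay.centre_rows, lay.centre_cols, along_cols=True)

    @property
    def n_avdus(self) -> dict[str, int]:
        return {name: (arr.n_detectors if arr is not None else 0)
                for name, arr in [("left", self.left), ("right", self.right),
                                  ("centre", self.centre)]}

    def _inputs(self, frame: np.ndarray) -> dict[str, np.ndarray | None]:
        lay = self.layout
        out: dict[str, np.ndarray | None] = {}
        if self.left is not None:
            # preferred direction: away from frame centre = decreasing column
            out["left"] = frame[_span(lay.left_rows), _span(lay.left_cols)][:, ::-1]
        else:
            out["left"] = None
        if self.right is not None:
            out["right"] = frame[_span(lay.right_rows), _span(lay.right_cols)]
        else:
            out["right"] = None
        if self.centre is not None:
            # ventral subregion: chains run down each column (decreasing row)
            sub = frame[_span(lay.centre_rows), _span(lay.centre_cols)]
            out["centre"] = sub[::-1, :].T
        else:
            out["centre"] = None
        return out

    def step(self, frame: np.ndarray) -> tuple[float, float, float]:
        """Advance all three arrays one dt; returns (S_L, S_R, S_C)."""
        inputs = self._inputs(np.asarray(frame, dtype=float))
        s = []
        for name, arr in [("left", self.left), ("right", self.right),
                          ("centre", self.centre)]:
            if arr is None:
                s.append(0.0)
            else:
                s.append(arr.step(inputs[name]).S)
        return s[0], s[1], s[2]

    def reset(self) -> None:
        for arr in (self.left, self.right, self.centre):
            if arr is not None:
                arr.reset()


def build_full_system(params: AVDUParams, layout: SubregionLayout | None = None,
                      dt: float = DT_MS) -> FullSystem:
    """Instantiate the closed-loop system (layout overlap is checked by the
    layout itself at construction)."""
    return FullSystem(params, layout, dt)
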