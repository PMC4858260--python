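"""Stimuli and virtual environments.

Two kinds of visual input drive the model:

* moving square-wave or sinusoidal gratings, point-sampled by the *test
  system*'s 100 x 2 grid of input locations (2 deg spacing along rows, a
  200 x 4 deg field of view), used for open-loop response curves;
* a patterned flight corridor rendered onto the *full system*'s 32 x 32
  ommatidial grid by ray casting, used for closed-loop behaviour.

Wall and floor patterns are specified as cycles per degree *as seen from the
corridor centre* and converted to cycles/cm on the surface.  The 32 x 32 eye
has roughly one fifth of the bee's angular resolution, so experiments present
spatial frequencies five times smaller than the bee-scale values they
emulate; :func:`bee_to_model_frequency` is that conversion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ConfigurationError

__all__ = [
    "Grating",
    "grating_luminance",
    "TestArrayGeometry",
    "sample_test_array",
    "bee_to_model_frequency",
    "model_to_bee_frequency",
    "SurfaceGrating",
    "CorridorWorld",
    "SubregionLayout",
    "BeePose",
    "CorridorRenderer",
    "render_corridor",
]

#: fivefold resolution reduction of the model eye relative to the bee eye
MODEL_EYE_SCALE = 5.0


def bee_to_model_frequency(f_bee: float) -> float:
    """Convert a bee-scale spatial frequency (c/deg) to the model scale."""
    return f_bee / MODEL_EYE_SCALE


def model_to_bee_frequency(f_model: float) -> float:
    """Inverse of :func:`bee_to_model_frequency`."""
    return f_model * MODEL_EYE_SCALE


# ---------------------------------------------------------------------------
# gratings and the open-loop test geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grating:
    """A drifting grating in angular coordinates.

    ``angular_velocity`` is signed (positive = preferred direction of the
    test array, increasing angle).  Luminance stays within [0, 1] for any
    Michelson ``contrast`` <= 1 around ``mean_luminance`` = 0.5.
    """

    waveform: str = "square"
    wavelength: float = 38.0  # deg
    angular_velocity: float = 100.0  # deg/s, signed
    contrast: float = 1.0
    mean_luminance: float = 0.5
    phase0: float = 0.0  # deg

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ConfigurationError("wavelength must be > 0")
        if self.waveform not in ("square", "sine"):
            raise ConfigurationError(f"unknown waveform {self.waveform!r}")
        if not 0.0 <= self.contrast <= 1.0:
            raise ConfigurationError("contrast must be in [0, 1]")

    @property
    def temporal_frequency(self) -> float:
        """Contrast cycles per second seen at a fixed point, Hz."""
        return abs(self.angular_velocity) / self.wavelength


def grating_luminance(g: Grating, angle, t: float):
    """Luminance of grating ``g`` at angular position(s) ``angle`` (deg), time t (s).

    The bright half-cycle of a square wave starts at phase 0.
    """
    phase = 2.0 * math.pi * (np.asarray(angle, dtype=float)
                             - g.angular_velocity * t - g.phase0) / g.wavelength
    if g.waveform == "sine":
        wave = np.sin(phase)
    else:
        wave = np.where(np.sin(phase) >= 0.0, 1.0, -1.0)
    out = g.mean_luminance * (1.0 + g.contrast * wave)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TestArrayGeometry:
    """The 100 x 2 open-loop sampling grid: 2 deg spacing along rows."""

    __test__ = False  # not a pytest class, despite the name

    n_rows: int = 2
    n_cols: int = 100
    spacing_deg: float = 2.0

    @property
    def n_locations(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_avdus(self) -> int:
        """Adjacent-pair rule: one detector per neighbouring pair in a row."""
        return self.n_rows * (self.n_cols - 1)

    @property
    def angles(self) -> np.ndarray:
        """Angular position of each column along the motion axis, deg."""
        return np.arange(self.n_cols) * self.spacing_deg


def sample_test_array(geom: TestArrayGeometry, g: Grating, t: float) -> np.ndarray:
    """Point-sample the grating at every receptor; shape (n_rows, n_cols).

    Rows are parallel to the motion axis, so both rows see identical samples.
    """
    row = grating_luminance(g, geom.angles, t)
    return np.broadcast_to(row, (geom.n_rows, geom.n_cols)).copy()


# ---------------------------------------------------------------------------
# the corridor world and ommatidial rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfaceGrating:
    """A grating painted along a corridor surface (stripes across the flight axis).

    ``frequency`` is in cycles per degree at the *model* scale, measured as
    the angular frequency seen from the corridor centre; the conversion to
    cycles/cm uses the centre-to-surface distance supplied by the world.
    """

    waveform: str = "square"
    frequency: float = 0.03  # c/deg, model scale
    contrast: float = 1.0
    mean_luminance: float = 0.5
    phase0_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise ConfigurationError("frequency must be >= 0")
        if self.waveform not in ("square", "sine"):
            raise ConfigurationError(f"unknown waveform {self.waveform!r}")

    def cycles_per_cm(self, centre_distance_cm: float) -> float:
        # 1 cm at the closest point subtends (1/dist) rad from the centre
        deg_per_cm = math.degrees(1.0 / centre_distance_cm)
        return self.frequency * deg_per_cm

    def luminance(self, y_cm, centre_distance_cm: float):
        if self.frequency == 0.0:
            return np.full_like(np.asarray(y_cm, dtype=float), self.mean_luminance)
        phase = 2.0 * math.pi * self.cycles_per_cm(centre_distance_cm) \
            * (np.asarray(y_cm, dtype=float) - self.phase0_cm)
        wave = np.sin(phase)
        if self.waveform == "square":
            wave = np.where(wave >= 0.0, 1.0, -1.0)
        return self.mean_luminance * (1.0 + self.contrast * wave)


UNIFORM = SurfaceGrating(frequency=0.0)


@dataclass(frozen=True)
class CorridorWorld:
    """A straight corridor with patterned walls and floor.

    x = 0 is the corridor midline (+x toward the right wall), z = 0 the
    floor, y runs along the corridor.  Patterns repeat indefinitely along y,
    so trials never run out of corridor.  The default floor pattern (0.02
    c/deg model scale, i.e. 0.1 c/deg bee scale) gives the ventral detectors
    optic flow for height control.
    """

    width: float = 20.0  # cm
    height: float = 20.0  # cm
    length: float = 300.0  # cm, nominal (patterns repeat along y)
    left_wall: SurfaceGrating = field(default_factory=SurfaceGrating)
    right_wall: SurfaceGrating = field(default_factory=SurfaceGrating)
    floor: SurfaceGrating = field(
        default_factory=lambda: SurfaceGrating(frequency=bee_to_model_frequency(0.1)))
    background_luminance: float = 0.5


@dataclass
class BeePose:
    """Agent state: lateral x (cm, 0 = midline, + toward right wall),
    height z (cm), along-corridor y (cm), forward speed v (cm/s)."""

    x: float = 0.0
    z: float = 6.0
    y: float = 0.0
    v: float = 40.0


@dataclass(frozen=True)
class SubregionLayout:
    """Retinotopic placement of the three full-system detector arrays.

    Indices are 1-based inclusive (row 1 = bottom of the eye).  Left/right
    subregions prefer horizontal motion away from the eye's centre column;
    the centre (ventral) subregion prefers downward motion along columns.
    The right subregion spans columns 21-32 so that each of its rows holds
    12 locations and therefore 11 detectors, matching the left subregion.
    """

    left_rows: tuple[int, int] = (9, 14)
    left_cols: tuple[int, int] = (1, 12)
    right_rows: tuple[int, int] = (9, 14)
    right_cols: tuple[int, int] = (21, 32)
    centre_rows: tuple[int, int] = (1, 6)
    centre_cols: tuple[int, int] = (13, 19)

    def __post_init__(self) -> None:
        boxes = [
            (self.left_rows, self.left_cols),
            (self.right_rows, self.right_cols),
            (self.centre_rows, self.centre_cols),
        ]
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                (r1, c1), (r2, c2) = boxes[i], boxes[j]
                if (r1[0] <= r2[1] and r2[0] <= r1[1]
                        and c1[0] <= c2[1] and c2[0] <= c1[1]):
                    raise ConfigurationError("subregions overlap")

    @staticmethod
    def empty() -> "SubregionLayout":
        """A degenerate layout with no detectors (testing aid)."""
        layout = object.__new__(SubregionLayout)
        for name in ("left_rows", "left_cols", "right_rows", "right_cols",
                     "centre_rows", "centre_cols"):
            object.__setattr__(layout, name, (0, -1))
        return layout


class CorridorRenderer:
    """Casts one ray per ommatidium of a 32 x 32 equirectangular eye.

    The eye spans 260 deg of azimuth by 180 deg of elevation, centred on the
    flight (+y) axis; azimuth is positive toward the right wall, and frame
    row 0 is the bottom (most ventral) row.  Because the corridor cross
    section is constant, ray hits for a given (x, z) are independent of y:
    the renderer caches, per ray, which surface is hit and the along-corridor
    offset of the hit point, and re-renders for a new y by evaluating the
    surface patterns only.  Rendering is exactly deterministic.
    """

    N = 32
    FOV_AZ = 260.0
    FOV_EL = 180.0

    def __init__(self, world: CorridorWorld):
        self.world = world
        n = self.N
        az = np.deg2rad(-self.FOV_AZ / 2 + (np.arange(n) + 0.5) * self.FOV_AZ / n)
        el = np.deg2rad(-self.FOV_EL / 2 + (np.arange(n) + 0.5) * self.FOV_EL / n)
        el_grid, az_grid = np.meshgrid(el, az, indexing="ij")  # [row, col], row 0 bottom
        self._dx = np.sin(az_grid) * np.cos(el_grid)
        self._dy = np.cos(az_grid) * np.cos(el_grid)
        self._dz = np.sin(el_grid)
        self._cache_key: tuple[float, float] | None = None
        self._surface_idx: np.ndarray | None = None
        self._y_offset: np.ndarray | None = None

    def _clamp_pose(self, pose: BeePose) -> tuple[float, float]:
        w, h = self.world.width, self.world.height
        x, z = pose.x, pose.z
        if not (-w / 2 < x < w / 2) or not (0 < z < h):
            warnings.warn("pose outside corridor volume; clamped", stacklevel=3)
            x = min(max(x, -w / 2 + 1e-6), w / 2 - 1e-6)
            z = min(max(z, 1e-6), h - 1e-6)
        return x, z

    def _build_cache(self, x: float, z: float) -> None:
        w, h = self.world.width, self.world.height
        big = np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            t_left = np.where(self._dx < 0, (-w / 2 - x) / self._dx, big)
            t_right = np.where(self._dx > 0, (w / 2 - x) / self._dx, big)
            t_floor = np.where(self._dz < 0, -z / self._dz, big)
            t_ceil = np.where(self._dz > 0, (h - z) / self._dz, big)
        ts = np.stack([t_left, t_right, t_floor, t_ceil])  # surfaces 0..3
        self._surface_idx = np.argmin(ts, axis=0)
        t_hit = np.min(ts, axis=0)
        # rays exactly parallel to all surfaces never hit: treat as background
        miss = ~np.isfinite(t_hit)
        self._surface_idx[miss] = 4
        self._y_offset = np.where(miss, 0.0, t_hit * self._dy)
        self._cache_key = (x, z)

    def render(self, pose: BeePose) -> np.ndarray:
        """Return the 32 x 32 luminance frame seen from ``pose``."""
        x, z = self._clamp_pose(pose)
        if self._cache_key != (x, z):
            self._build_cache(x, z)
        w = self.world
        y_hit = pose.y + self._y_offset
        frame = np.full((self.N, self.N), w.background_luminance)
        half_w, half_h = w.width / 2.0, w.height / 2.0
        for idx, (pattern, dist) in enumerate([
                (w.left_wall, half_w), (w.right_wall, half_w), (w.floor, half_h)]):
            mask = self._surface_idx == idx
            if mask.any():
                frame[mask] = pattern.luminance(y_hit[mask], dist)
        # surface 3 (ceiling) and misses keep the background luminance
        return frame


def render_corridor(world: CorridorWorld, pose: BeePose) -> np.ndarray:
    """One-shot render of the ommatidial frame (see :class:`CorridorRenderer`)."""
    return CorridorRenderer(world).render(pose)
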