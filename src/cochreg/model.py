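"""Parametric cochlear lateral-wall centerline.

The cochlea is modelled as a coiling spiral centered at the origin whose
basal-turn footprint is fixed by four quadrant extents: walking
counter-clockwise (seen from the apex) the lateral wall passes at distance
``A_a`` from the center on the +x axis (0°), ``B_a`` on the +y axis (90°),
``A_b`` on the -x axis (180°) and ``B_b`` on the -y axis (270°).  Radius at
unwound angle θ (degrees, 0 at the basal start) is

    r(θ) = q(θ mod 360°) · d^(θ / 360°)

where ``q`` is a periodic cubic through the four quadrant anchors (corrected
for the within-turn decay so the first-turn anchors are hit exactly) and
``d`` is the per-turn radial decay factor.  Height grows linearly with θ from
0 at the base to ``height`` at the apex.  All coordinates are millimetres in
a right-handed frame with the coiling axis along z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ParameterError

__all__ = [
    "CochlearParams",
    "Centerline",
    "MEAN_QUADRANT_PARAMS",
    "DEFAULT_DECAY",
    "DEFAULT_HEIGHT_MM",
    "mean_params",
    "compute_turns",
    "planar_radius",
    "centerline_point",
    "build_centerline",
    "point_at_angle",
]

#: Quadrant extents (A_a, A_b, B_a, B_b) of the average human cochlea, mm.
MEAN_QUADRANT_PARAMS = (5.97, 3.26, 3.95, 2.85)

#: Per-turn radial decay factor of the spiral.
DEFAULT_DECAY = 0.6

#: Default apical height of the model, mm.
DEFAULT_HEIGHT_MM = 4.0

# Turns calibration: turns = base + slope * ln((A_a+A_b)/(B_a+B_b)), chosen so
# the mean cochlea gets 2.70 turns.  With landmarks every 90° that yields 12
# landmarks, the last one at the end of the turn less than 90° past the 11th.
_TURNS_SLOPE = 1.0
_TURNS_AT_MEAN = 2.70
_TURNS_BASE = _TURNS_AT_MEAN - _TURNS_SLOPE * math.log(
    (MEAN_QUADRANT_PARAMS[0] + MEAN_QUADRANT_PARAMS[1])
    / (MEAN_QUADRANT_PARAMS[2] + MEAN_QUADRANT_PARAMS[3])
)
_TURNS_MIN, _TURNS_MAX = 1.6, 3.4  # clamp keeps turns inside (1.5, 3.5)


def compute_turns(A_a: float, A_b: float, B_a: float, B_b: float) -> float:
    """Number of spiral turns implied by the four quadrant extents.

    The dependence is shape-only: it uses the log-ratio of the A-axis to the
    B-axis footprint, so scaling all four extents by a common factor leaves
    the result unchanged.  The value is clamped to a plausible anatomical
    range inside (1.5, 3.5) turns.
    """
    for name, v in (("A_a", A_a), ("A_b", A_b), ("B_a", B_a), ("B_b", B_b)):
        if not v > 0:
            raise ParameterError(f"quadrant extent {name} must be > 0, got {v!r}")
    t = _TURNS_BASE + _TURNS_SLOPE * math.log((A_a + A_b) / (B_a + B_b))
    return float(min(max(t, _TURNS_MIN), _TURNS_MAX))


@dataclass(frozen=True)
class CochlearParams:
    """Quadrant extents (mm), number of turns and apical height of a cochlea.

    ``turns`` may be given explicitly (e.g. estimated from a patient scan);
    when omitted it is computed from the four quadrant extents.
    """

    A_a: float
    A_b: float
    B_a: float
    B_b: float
    turns: float = None  # type: ignore[assignment]  # filled in __post_init__
    height: float = DEFAULT_HEIGHT_MM

    def __post_init__(self) -> None:
        for name in ("A_a", "A_b", "B_a", "B_b"):
            if not getattr(self, name) > 0:
                raise ParameterError(
                    f"quadrant extent {name} must be > 0, got {getattr(self, name)!r}"
                )
        if self.turns is None:
            object.__setattr__(
                self, "turns", compute_turns(self.A_a, self.A_b, self.B_a, self.B_b)
            )
        if not self.turns > 1:
            raise ParameterError(f"turns must be > 1, got {self.turns!r}")
        if not self.height > 0:
            raise ParameterError(f"height must be > 0, got {self.height!r}")

    @property
    def total_angle_deg(self) -> float:
        return 360.0 * self.turns

    def with_turns(self, turns: float) -> "CochlearParams":
        """Return a copy with the number of turns overridden."""
        return replace(self, turns=turns)


def mean_params(turns: float | None = None, height: float = DEFAULT_HEIGHT_MM) -> CochlearParams:
    """The average cochlea: A_a=5.97, A_b=3.26, B_a=3.95, B_b=2.85 mm."""
    A_a, A_b, B_a, B_b = MEAN_QUADRANT_PARAMS
    return CochlearParams(A_a, A_b, B_a, B_b, turns=turns, height=height)


def _quadrant_spline(params: CochlearParams, decay: float) -> CubicSpline:
    # Anchor values are divided by the decay already accrued at the anchor's
    # first-turn angle, so r(θ) = q(θ mod 360)·d^(θ/360) hits the quadrant
    # extents exactly at 0°, 90°, 180°, 270°.
    phases = np.array([0.0, 90.0, 180.0, 270.0, 360.0])
    anchors = np.array(
        [params.A_a, params.B_a, params.A_b, params.B_b, params.A_a]
    ) / decay ** (phases / 360.0)
    anchors[-1] = anchors[0]  # exact periodicity
    return CubicSpline(phases, anchors, bc_type="periodic")


def planar_radius(
    params: CochlearParams, theta_deg: float | np.ndarray, decay: float = DEFAULT_DECAY
) -> float | np.ndarray:
    """Distance from the coiling (z) axis at unwound angle ``theta_deg``."""
    if not 0 < decay < 1:
        raise ParameterError(f"decay must be in (0, 1), got {decay!r}")
    theta = np.asarray(theta_deg, dtype=float)
    q = _quadrant_spline(params, decay)
    r = q(np.mod(theta, 360.0)) * decay ** (theta / 360.0)
    return float(r) if np.isscalar(theta_deg) else r


def centerline_point(
    params: CochlearParams, theta_deg: float | np.ndarray, decay: float = DEFAULT_DECAY
) -> np.ndarray:
    """Exact lateral-wall point(s) at unwound angle(s), shape (3,) or (m, 3)."""
    theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    r = planar_radius(params, theta, decay)
    phi = np.deg2rad(theta)
    z = params.height * theta / params.total_angle_deg
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts[0] if np.isscalar(theta_deg) else pts


@dataclass(frozen=True)
class Centerline:
    """Sampled lateral-wall centerline: points (m, 3) mm and unwound angles (deg)."""

    points: np.ndarray
    angles_deg: np.ndarray
    params: CochlearParams | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        ang = np.asarray(self.angles_deg, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] != ang.shape[0]:
            raise ParameterError("centerline needs matching (m, 3) points and m angles")
        if pts.shape[0] < 2:
            raise ParameterError("centerline needs at least two samples")
        if not np.all(np.diff(ang) > 0):
            raise ParameterError("centerline angles must be strictly increasing")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "angles_deg", ang)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def total_angle_deg(self) -> float:
        return float(self.angles_deg[-1])


def build_centerline(
    params: CochlearParams,
    samples_per_turn: int = 72,
    decay: float = DEFAULT_DECAY,
) -> Centerline:
    """Sample the spiral from the basal start (θ=0) to the apex (θ=360·turns).

    ``samples_per_turn`` controls angular resolution; the default (72, i.e.
    one sample every 5°) makes all 45°/90°/180° landmark angles exact samples.
    """
    if samples_per_turn < 8:
        raise ParameterError(f"samples_per_turn must be >= 8, got {samples_per_turn!r}")
    total = params.total_angle_deg
    # exact multiples of the angular step, plus the terminal (apex) angle
    step = 360.0 / samples_per_turn
    angles = np.arange(0.0, total, step)
    if total - angles[-1] < 1e-9:
        angles[-1] = total
    else:
        angles = np.append(angles, total)
    return Centerline(centerline_point(params, angles, decay), angles, params=params)


def point_at_angle(centerline: Centerline, theta_deg: float) -> np.ndarray:
    """Point on the sampled centerline at ``theta_deg``, linearly interpolated.

    Exact at sampled angles; raises for angles outside [0, 360·turns].
    """
    ang = centerline.angles_deg
    if not ang[0] <= theta_deg <= ang[-1]:
        raise ParameterError(
            f"angle {theta_deg!r} outside centerline range [{ang[0]}, {ang[-1]}]"
        )
    return np.array(
        [np.interp(theta_deg, ang, centerline.points[:, k]) for k in range(3)]
    )
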