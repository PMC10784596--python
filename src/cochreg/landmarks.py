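"""Ordered landmark sets and angular placement schemes.

Landmarks carry 1-based ordinal labels and their order establishes the
correspondence between the model side and the patient side: landmark *i* on
the model always answers landmark *i* on the (segmented or raw) CT.  The
order is therefore preserved by every operation here, and paired deletions
remove the same indices from both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CorrespondenceError, GeometryError, ParameterError
from .model import Centerline, CochlearParams, point_at_angle

__all__ = [
    "LandmarkSet",
    "PlacementScheme",
    "placement_angles",
    "place_landmarks",
    "estimate_quadrant_params",
    "delete_landmarks",
]

_SOURCES = ("model", "segmented", "ct")


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered 3D landmarks in mm with consecutive 1-based labels."""

    points: np.ndarray
    labels: tuple[int, ...] = ()
    source: str = "model"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ParameterError(f"landmark points must be (n, 3), got {pts.shape}")
        labels = tuple(self.labels) if self.labels else tuple(range(1, len(pts) + 1))
        if labels != tuple(range(1, len(pts) + 1)):
            raise ParameterError("labels must be consecutive integers starting at 1")
        if len(pts) > 1 and len(np.unique(pts, axis=0)) != len(pts):
            raise ParameterError("duplicate landmark points are not allowed")
        if self.source not in _SOURCES:
            raise ParameterError(f"source must be one of {_SOURCES}, got {self.source!r}")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.points.shape[0]

    def point(self, label: int) -> np.ndarray:
        """The point carrying ``label`` (1-based)."""
        if label not in self.labels:
            raise ParameterError(f"no landmark with label {label}")
        return self.points[label - 1]

    def with_points(self, points: np.ndarray, source: str | None = None) -> "LandmarkSet":
        return LandmarkSet(points, source=source or self.source)


@dataclass(frozen=True)
class PlacementScheme:
    """Angular landmark placement: every ``spacing`` degrees, or the minimal
    5-landmark scheme (0°, 90°, 180°, 270° on the basal turn plus the apex)."""

    spacing: float | None = 90.0
    minimal5: bool = False
    include_terminal: bool = True

    def __post_init__(self) -> None:
        if self.minimal5:
            return
        if self.spacing is None or not self.spacing > 0:
            raise ParameterError("spacing must be positive (or use minimal5)")
        if abs(360.0 / self.spacing - round(360.0 / self.spacing)) > 1e-9:
            raise ParameterError(f"spacing must divide 360°, got {self.spacing!r}")

    @classmethod
    def minimal(cls) -> "PlacementScheme":
        return cls(spacing=None, minimal5=True)


def placement_angles(total_angle_deg: float, scheme: PlacementScheme) -> np.ndarray:
    """Unwound angles (deg) at which a scheme places landmarks.

    Regular landmarks sit at multiples of the spacing; a terminal landmark is
    added at the end of the last turn.  When the terminal gap is shorter than
    half the spacing, the terminal landmark replaces the final multiple, so
    landmarks never crowd closer than half the nominal spacing.
    """
    total = float(total_angle_deg)
    if total <= 0:
        raise GeometryError("total angle must be positive")
    if scheme.minimal5:
        if total <= 270.0:
            raise GeometryError("minimal5 scheme needs more than 270° of spiral")
        return np.array([0.0, 90.0, 180.0, 270.0, total])
    step = float(scheme.spacing)
    m = int(np.floor(total / step + 1e-9))
    gap = total - m * step
    angles = list(np.arange(m + 1) * step)
    if gap > 1e-9 and scheme.include_terminal:
        if gap < step / 2.0:
            angles[-1] = total  # terminal replaces the last (too close) multiple
        else:
            angles.append(total)
    return np.asarray(angles)


def place_landmarks(centerline: Centerline, scheme: PlacementScheme) -> LandmarkSet:
    """Place ordered landmarks on the model lateral wall under a scheme."""
    angles = placement_angles(centerline.total_angle_deg, scheme)
    pts = np.vstack([point_at_angle(centerline, a) for a in angles])
    return LandmarkSet(pts, source="model")


def _closest_point_to_lines(
    anchors: np.ndarray, directions: np.ndarray
) -> np.ndarray:
    # Least-squares point M minimizing sum of squared distances to the lines
    # a_i + t d_i: solve  Σ(I - d_i d_iᵀ) M = Σ(I - d_i d_iᵀ) a_i.
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for a, d in zip(anchors, directions):
        P = np.eye(3) - np.outer(d, d)
        A += P
        b += P @ a
    return np.linalg.solve(A, b)


def estimate_quadrant_params(
    P1: np.ndarray,
    P2: np.ndarray,
    Q1: np.ndarray,
    Q2: np.ndarray,
    return_center: bool = False,
):
    """Quadrant extents from two basal-turn chords picked in a scan.

    ``P1``/``P2`` span the long (A) axis of the basal turn, ``Q1``/``Q2`` the
    perpendicular (B) axis.  The spiral center M is the least-squares closest
    point to the two chord lines (their intersection when coplanar), and the
    extents are the distances A_a=|P1−M|, A_b=|M−P2|, B_a=|Q1−M|, B_b=|M−Q2|.

    Returns a :class:`CochlearParams` (turns computed from the estimated
    extents); with ``return_center=True`` returns ``(params, M)``.
    """
    P1, P2, Q1, Q2 = (np.asarray(p, dtype=float) for p in (P1, P2, Q1, Q2))
    d1 = P2 - P1
    d2 = Q2 - Q1
    n1, n2 = np.linalg.norm(d1), np.linalg.norm(d2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise GeometryError("chord endpoints must be distinct")
    d1, d2 = d1 / n1, d2 / n2
    if np.linalg.norm(np.cross(d1, d2)) < 1e-9:
        raise GeometryError("chords are parallel; center is undetermined")
    M = _closest_point_to_lines(np.array([P1, Q1]), np.array([d1, d2]))
    params = CochlearParams(
        A_a=float(np.linalg.norm(P1 - M)),
        A_b=float(np.linalg.norm(M - P2)),
        B_a=float(np.linalg.norm(Q1 - M)),
        B_b=float(np.linalg.norm(M - Q2)),
    )
    return (params, M) if return_center else params


def delete_landmarks(
    lm_pair: tuple[LandmarkSet, LandmarkSet], labels: "set[int] | list[int]"
) -> tuple[LandmarkSet, LandmarkSet]:
    """Remove the same labels from both corresponding sets.

    Remaining landmarks are re-numbered consecutively from 1; the i-th
    surviving pair is the same pair as before deletion.
    """
    lm, lc = lm_pair
    if len(lm) != len(lc):
        raise CorrespondenceError(
            f"corresponding sets differ in length: {len(lm)} vs {len(lc)}"
        )
    labels = sorted(set(int(l) for l in labels))
    for l in labels:
        if l not in lm.labels:
            raise ParameterError(f"label {l} not present (n={len(lm)})")
    keep = [i for i in range(len(lm)) if (i + 1) not in labels]
    return (
        LandmarkSet(lm.points[keep], source=lm.source),
        LandmarkSet(lc.points[keep], source=lc.source),
    )
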