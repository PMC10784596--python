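"""Affine landmark registration by quasi-Newton SSD minimization.

The model-to-patient map is the composition

    f_T = f_F ∘ f_{R,t} ∘ f_C ∘ f_S

applied to a point as: shear, then anisotropic scale, then rotation plus
translation, then axis reflection.  The continuous parameter vector

    p* = (α, β, γ, t_x, t_y, t_z, c_x, c_y, c_z, s_xy, s_xz, s_yz)

is optimized by a quasi-Newton (BFGS) descent on the sum of squared
differences between transformed model landmarks and their corresponding
patient landmarks, starting from the identity and stopping when the SSD
change between accepted iterations falls below a tolerance (default 1e-6
mm²) or a maximum iteration count is reached.  Reflection is discrete (three
axis sign flags outside p*); an optional exhaustive search tries all eight
sign assignments and keeps the best fit.

Internally the scale factors are optimized on a log scale so they stay
strictly positive; the reported parameters are the plain factors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .errors import (
    CorrespondenceError,
    GeometryError,
    ParameterError,
    UnderdeterminedError,
)
from .landmarks import LandmarkSet
from .model import Centerline

__all__ = [
    "AffineParams",
    "RegistrationResult",
    "compose_transform",
    "ssd",
    "register",
    "mae",
    "apply_transform",
    "affine_least_squares",
]

_IDENTITY_VECTOR = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=float)


@dataclass(frozen=True)
class AffineParams:
    """The 12 continuous affine parameters plus discrete reflection flags.

    Angles are radians, translations mm, scales and shears dimensionless.
    ``reflection`` holds one sign in {+1, -1} per axis and sits outside the
    continuous parameter vector.
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    t_x: float = 0.0
    t_y: float = 0.0
    t_z: float = 0.0
    c_x: float = 1.0
    c_y: float = 1.0
    c_z: float = 1.0
    s_xy: float = 0.0
    s_xz: float = 0.0
    s_yz: float = 0.0
    reflection: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if not (self.c_x > 0 and self.c_y > 0 and self.c_z > 0):
            raise ParameterError("scale factors must be strictly positive")
        if any(f not in (1, -1) for f in self.reflection):
            raise ParameterError("reflection flags must be +1 or -1")

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls()

    @classmethod
    def from_vector(
        cls, p: np.ndarray, reflection: tuple[int, int, int] = (1, 1, 1)
    ) -> "AffineParams":
        """Build from the 12-vector p* (order: angles, t, scales, shears)."""
        p = np.asarray(p, dtype=float)
        if p.shape != (12,):
            raise ParameterError(f"p* must have 12 entries, got shape {p.shape}")
        return cls(*p, reflection=tuple(int(f) for f in reflection))

    def to_vector(self) -> np.ndarray:
        return np.array(
            [
                self.alpha, self.beta, self.gamma,
                self.t_x, self.t_y, self.t_z,
                self.c_x, self.c_y, self.c_z,
                self.s_xy, self.s_xz, self.s_yz,
            ]
        )


def _rotations(a: float, b: float, g: float):
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    cg, sg = math.cos(g), math.sin(g)
    Rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rz = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    dRx = np.array([[0, 0, 0], [0, -sa, -ca], [0, ca, -sa]])
    dRy = np.array([[-sb, 0, cb], [0, 0, 0], [-cb, 0, -sb]])
    dRz = np.array([[-sg, -cg, 0], [cg, -sg, 0], [0, 0, 0]])
    return Rx, Ry, Rz, dRx, dRy, dRz


def _shear(s_xy: float, s_xz: float, s_yz: float) -> np.ndarray:
    return np.array([[1.0, s_xy, s_xz], [0.0, 1.0, s_yz], [0.0, 0.0, 1.0]])


def _linear_parts(p: np.ndarray, reflection) -> tuple[np.ndarray, np.ndarray]:
    """Linear map A and offset b of the composed transform (no validation)."""
    a, b_, g, tx, ty, tz, cx, cy, cz, sxy, sxz, syz = p
    Rx, Ry, Rz, _, _, _ = _rotations(a, b_, g)
    R = Rz @ Ry @ Rx
    F = np.diag(np.asarray(reflection, dtype=float))
    A = F @ R @ np.diag([cx, cy, cz]) @ _shear(sxy, sxz, syz)
    b = F @ np.array([tx, ty, tz])
    return A, b


def compose_transform(params: AffineParams) -> np.ndarray:
    """The 4×4 homogeneous matrix of f_F ∘ f_{R,t} ∘ f_C ∘ f_S."""
    A, b = _linear_parts(params.to_vector(), params.reflection)
    T = np.eye(4)
    T[:3, :3] = A
    T[:3, 3] = b
    return T


def apply_transform(matrix: np.ndarray, obj):
    """Apply a 4×4 homogeneous transform to landmarks, a centerline or points.

    Labels and ordering are unchanged; the return type matches the input.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ParameterError(f"expected a 4x4 matrix, got shape {matrix.shape}")
    if not np.allclose(matrix[3], [0, 0, 0, 1]):
        raise ParameterError("last row of a homogeneous transform must be (0,0,0,1)")
    A, b = matrix[:3, :3], matrix[:3, 3]
    if isinstance(obj, LandmarkSet):
        return obj.with_points(obj.points @ A.T + b)
    if isinstance(obj, Centerline):
        return Centerline(obj.points @ A.T + b, obj.angles_deg, params=obj.params)
    pts = np.asarray(obj, dtype=float)
    return pts @ A.T + b


def ssd(l_M: LandmarkSet, l_C: LandmarkSet, params: AffineParams) -> float:
    """Sum of squared distances Σ ||f_T(l_M,i) − l_C,i||² in mm²."""
    if len(l_M) != len(l_C):
        raise CorrespondenceError(
            f"landmark sets must correspond 1:1, got {len(l_M)} vs {len(l_C)}"
        )
    A, b = _linear_parts(params.to_vector(), params.reflection)
    r = l_M.points @ A.T + b - l_C.points
    return float(np.sum(r * r))


def mae(per_landmark_error) -> float:
    """Mean absolute error: arithmetic mean of per-landmark distances, mm."""
    if isinstance(per_landmark_error, dict):
        per_landmark_error = list(per_landmark_error.values())
    errs = np.asarray(per_landmark_error, dtype=float)
    if errs.size == 0:
        raise ParameterError("per-landmark error list must be non-empty")
    return float(np.mean(errs))


@dataclass(frozen=True)
class RegistrationResult:
    """Optimal transform with its convergence and error diagnostics."""

    params: AffineParams
    matrix: np.ndarray
    iterations: int
    ssd_history: tuple[float, ...]
    per_landmark_error: dict[int, float]
    mae: float

    @property
    def final_ssd(self) -> float:
        return self.ssd_history[-1]


# ---------------------------------------------------------------------------
# quasi-Newton minimization of the SSD objective
# ---------------------------------------------------------------------------

# In the internal optimization vector the scale entries 6..8 hold log(c) so a
# line search can never cross zero scale; _expand maps back to plain p*.  The
# clip bounds only guard line-search trial points against overflow.


def _expand(u: np.ndarray) -> np.ndarray:
    p = u.copy()
    p[6:9] = np.exp(np.clip(u[6:9], -30.0, 30.0))
    return p


def _objective_and_grad(u: np.ndarray, X: np.ndarray, Y: np.ndarray, refl):
    p = _expand(u)
    a, b_, g, tx, ty, tz, cx, cy, cz, sxy, sxz, syz = p
    Rx, Ry, Rz, dRx, dRy, dRz = _rotations(a, b_, g)
    R = Rz @ Ry @ Rx
    C = np.diag([cx, cy, cz])
    S = _shear(sxy, sxz, syz)
    F = np.diag(np.asarray(refl, dtype=float))
    CS = C @ S
    A = F @ R @ CS
    t = np.array([tx, ty, tz])
    res = X @ A.T + (F @ t) - Y  # (n, 3)
    f = float(np.sum(res * res))

    grad = np.empty(12)
    XT = X  # alias for readability

    def dA_dot(dA: np.ndarray) -> float:
        return 2.0 * float(np.sum((XT @ dA.T) * res))

    # rotation angles
    grad[0] = dA_dot(F @ (Rz @ Ry @ dRx) @ CS)
    grad[1] = dA_dot(F @ (Rz @ dRy @ Rx) @ CS)
    grad[2] = dA_dot(F @ (dRz @ Ry @ Rx) @ CS)
    # translation: d(res)/dt_j = F e_j, constant over landmarks
    rsum = 2.0 * res.sum(axis=0)
    grad[3:6] = F.T @ rsum  # F diagonal, F.T = F
    # scales (chain rule through log-parameterization: d/du = c · d/dc)
    FR = F @ R
    for j, c in enumerate((cx, cy, cz)):
        E = np.zeros((3, 3))
        E[j, j] = 1.0
        grad[6 + j] = dA_dot(FR @ E @ S) * c
    # shears
    FRC = FR @ C
    for k, (i, j) in enumerate(((0, 1), (0, 2), (1, 2))):
        E = np.zeros((3, 3))
        E[i, j] = 1.0
        grad[9 + k] = dA_dot(FRC @ E)
    return f, grad


def _minimize_one(Xc, Yc, refl, tol, max_iterations, p0):
    """One BFGS descent on centered data from the parameter vector ``p0``.

    Returns the optimal (centered-frame) p* and the list of accepted-iterate
    SSD values, whose entries are valid SSDs of the equivalent original-frame
    transforms (centering changes only the translation bookkeeping, not the
    residuals).
    """
    u0 = np.asarray(p0, dtype=float).copy()
    u0[6:9] = np.log(u0[6:9])

    history = [_objective_and_grad(u0, Xc, Yc, refl)[0]]

    def fun(u):
        return _objective_and_grad(u, Xc, Yc, refl)

    def callback(uk):
        fk = _objective_and_grad(uk, Xc, Yc, refl)[0]
        stop = abs(history[-1] - fk) < tol
        history.append(fk)
        if stop:
            raise StopIteration

    result = minimize(
        fun,
        u0,
        jac=True,
        method="BFGS",
        callback=callback,
        options={"maxiter": max_iterations, "gtol": 1e-14},
    )
    p = _expand(np.asarray(result.x, dtype=float))
    f_final = _objective_and_grad(result.x, Xc, Yc, refl)[0]
    if f_final < history[-1]:
        history.append(f_final)
    return p, history


# Quasi-Newton starts: the identity plus a half-turn about each axis.  The
# SSD landscape over Euler angles is multimodal for large rotations; these
# four proper-rotation starts cover its basins the same way the optional
# reflection search covers the improper ones.
_ROTATION_STARTS = (
    (0.0, 0.0, 0.0),
    (math.pi, 0.0, 0.0),
    (0.0, math.pi, 0.0),
    (0.0, 0.0, math.pi),
)


def _shift_translation(p: np.ndarray, refl, delta: np.ndarray) -> np.ndarray:
    """Return p* with the translation adjusted so the transform's offset
    changes by ``delta`` (the offset is F·t, F its own inverse)."""
    q = p.copy()
    F = np.asarray(refl, dtype=float)
    q[3:6] = q[3:6] + F * delta
    return q


def register(
    l_M: LandmarkSet,
    l_C: LandmarkSet,
    tol: float = 1e-6,
    max_iterations: int = 100,
    reflection_search: bool = False,
    reflection: tuple[int, int, int] = (1, 1, 1),
    x0: AffineParams | None = None,
    rotation_multistart: bool = True,
) -> RegistrationResult:
    """Fit the affine transform mapping model landmarks onto target landmarks.

    Parameters
    ----------
    l_M, l_C
        Corresponding ordered landmark sets (model and patient side), equal
        length n ≥ 4, model points affinely independent (rank 3).
    tol
        Stop when the SSD change between accepted quasi-Newton iterations
        falls below this value (mm²).
    max_iterations
        Iteration cap if the tolerance is never met.
    reflection_search
        When true, all 8 axis-sign assignments are optimized and the lowest
        final SSD wins; otherwise ``reflection`` is used as given.
    x0
        Optional warm start; by default p* starts at the identity values.
    rotation_multistart
        Also try half-turn rotation starts (ignored when ``x0`` is given);
        needed for global convergence when the pose rotation is large.

    Notes
    -----
    The descent runs on centroid-centered copies of both point sets, which
    leaves the residuals (and hence every reported SSD) unchanged but
    conditions the translation search; the translation is mapped back to the
    original frame afterwards.  Reported iterations are the accepted
    quasi-Newton iterations of the winning descent.
    """
    if len(l_M) != len(l_C):
        raise CorrespondenceError(
            f"landmark sets must correspond 1:1, got {len(l_M)} vs {len(l_C)}"
        )
    n = len(l_M)
    if n < 4:
        raise UnderdeterminedError(
            f"at least 4 landmark pairs are required, got {n}"
        )
    X, Y = l_M.points, l_C.points
    mu_X, mu_Y = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mu_X, Y - mu_Y
    if np.linalg.matrix_rank(Xc, tol=1e-9) < 3:
        raise GeometryError(
            "model landmarks are coplanar/collinear; affine fit is rank-deficient"
        )

    refl_candidates = (
        list(itertools.product((1, -1), repeat=3))
        if reflection_search
        else [tuple(reflection)]
    )
    best = None
    for refl in refl_candidates:
        if x0 is not None:
            # express the warm start in the centered frame: same linear part,
            # offset shifted by A·mu_X − mu_Y
            A0, _ = _linear_parts(x0.to_vector(), refl)
            starts = [_shift_translation(x0.to_vector(), refl, A0 @ mu_X - mu_Y)]
        else:
            angle_starts = _ROTATION_STARTS if rotation_multistart else _ROTATION_STARTS[:1]
            starts = [
                np.array([*ang, 0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=float)
                for ang in angle_starts
            ]
        for p0 in starts:
            p, history = _minimize_one(Xc, Yc, refl, tol, max_iterations, p0)
            if best is None or history[-1] < best[2][-1]:
                best = (p, refl, history)
    p, refl, history = best

    # translation back to the original frame: offset gains mu_Y − A·mu_X
    A_opt, _ = _linear_parts(p, refl)
    p = _shift_translation(p, refl, mu_Y - A_opt @ mu_X)
    params = AffineParams.from_vector(p, reflection=refl)
    matrix = compose_transform(params)
    transformed = apply_transform(matrix, l_M)
    errs = np.linalg.norm(transformed.points - Y, axis=1)
    per_landmark = {lab: float(e) for lab, e in zip(l_M.labels, errs)}
    return RegistrationResult(
        params=params,
        matrix=matrix,
        iterations=len(history) - 1,
        ssd_history=tuple(history),
        per_landmark_error=per_landmark,
        mae=mae(errs),
    )


def affine_least_squares(
    l_M: LandmarkSet, l_C: LandmarkSet
) -> tuple[np.ndarray, float]:
    """Closed-form unrestricted affine least-squares fit (reference/diagnostic).

    Solves the linear system [X | 1] W ≈ Y column-wise and returns the 4×4
    matrix and its SSD.  ``register`` never uses this; the parametric
    quasi-Newton fit should agree with it on non-degenerate inputs because
    reflection·rotation·scale·shear spans all invertible linear maps.
    """
    if len(l_M) != len(l_C):
        raise CorrespondenceError("landmark sets must correspond 1:1")
    X, Y = l_M.points, l_C.points
    H = np.column_stack([X, np.ones(len(X))])
    W, *_ = np.linalg.lstsq(H, Y, rcond=None)
    T = np.eye(4)
    T[:3, :3] = W[:3].T
    T[:3, 3] = W[3]
    res = H @ W - Y
    return T, float(np.sum(res * res))
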