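"""Iterative worst-landmark pruning.

The case-study workflow: register, rank landmarks by their residual
Euclidean error, delete the worst batch from both sides, re-register, and
repeat per a pruning plan.  Labels that must survive (typically the apical
landmark, which anchors the cochlea's height) can be protected; when a
protected landmark tops the error ranking the next-worst deletable one is
removed instead.  The report records every step with the landmarks' ORIGINAL
labels so deletions can be traced across the renumbering that follows each
batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, PruningPlanError
from .landmarks import LandmarkSet, delete_landmarks
from .registration import AffineParams, RegistrationResult, register

__all__ = [
    "PruningPlan",
    "PruneStep",
    "CaseReport",
    "rank_by_error",
    "prune",
    "reduction_percent",
]


def rank_by_error(result: RegistrationResult) -> list[int]:
    """Labels sorted by per-landmark error, worst first; ties → lower label."""
    return [
        lab
        for lab, _ in sorted(
            result.per_landmark_error.items(), key=lambda kv: (-kv[1], kv[0])
        )
    ]


def reduction_percent(mae_old: float, mae_new: float) -> float:
    """Percent error reduction 100·(1 − new/old), rounded to 2 decimals."""
    if not mae_old > 0:
        raise ParameterError(f"reference MAE must be positive, got {mae_old!r}")
    return round(100.0 * (1.0 - mae_new / mae_old), 2)


@dataclass(frozen=True)
class PruningPlan:
    """Deletion schedule: batch sizes, a floor on the pair count, and labels
    that are never deleted (original labels of the initial set)."""

    batch_sizes: tuple[int, ...] = ()
    min_landmarks: int = 4
    protected: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "batch_sizes", tuple(int(b) for b in self.batch_sizes))
        object.__setattr__(self, "protected", frozenset(int(l) for l in self.protected))
        if any(b < 1 for b in self.batch_sizes):
            raise ParameterError("batch sizes must be positive integers")
        if self.min_landmarks < 4:
            raise ParameterError("min_landmarks must be at least 4")


@dataclass(frozen=True)
class PruneStep:
    """One registration step of a pruning run (labels are original labels)."""

    remaining: tuple[int, ...]
    deleted: tuple[int, ...]
    mae: float
    iterations: int
    ssd: float
    result: RegistrationResult = field(repr=False, compare=False)


@dataclass(frozen=True)
class CaseReport:
    """All steps of a pruning run plus step-to-step percent MAE reductions."""

    steps: tuple[PruneStep, ...]
    reductions: dict[str, float]

    def reduction(self, i: int, j: int) -> float:
        """Percent MAE reduction from step i to step j (full precision input)."""
        return reduction_percent(self.steps[i].mae, self.steps[j].mae)


def prune(
    l_M: LandmarkSet,
    l_C: LandmarkSet,
    plan: PruningPlan,
    warm_start: bool = False,
    **register_opts,
) -> CaseReport:
    """Run the register → rank → delete-worst loop under a pruning plan.

    Each batch deletes the ``batch_size`` highest-error non-protected
    landmarks (truncated so the pair count never drops below
    ``plan.min_landmarks``), then re-registers.  Re-registration restarts
    from the identity unless ``warm_start`` is set, in which case the
    previous optimum seeds the quasi-Newton descent.  Extra keyword options
    are passed to :func:`cochreg.registration.register`.
    """
    if plan.protected - set(l_M.labels):
        raise ParameterError(
            f"protected labels {sorted(plan.protected - set(l_M.labels))} not in the set"
        )
    orig = list(l_M.labels)  # current index -> original label
    res = register(l_M, l_C, **register_opts)
    steps = [
        PruneStep(tuple(orig), (), res.mae, res.iterations, res.final_ssd, res)
    ]
    for batch in plan.batch_sizes:
        n = len(l_M)
        if n <= plan.min_landmarks:
            break
        k = min(batch, n - plan.min_landmarks)
        ranked = rank_by_error(res)  # current labels, worst first
        deletable = [lab for lab in ranked if orig[lab - 1] not in plan.protected]
        if len(deletable) < k:
            raise PruningPlanError(
                f"cannot delete {k} landmarks: only {len(deletable)} are unprotected"
            )
        drop = sorted(deletable[:k])
        dropped_orig = tuple(orig[lab - 1] for lab in drop)
        l_M, l_C = delete_landmarks((l_M, l_C), drop)
        orig = [o for i, o in enumerate(orig) if (i + 1) not in drop]
        opts = dict(register_opts)
        if warm_start:
            opts["x0"] = res.params
            opts.setdefault("reflection", res.params.reflection)
        res = register(l_M, l_C, **opts)
        steps.append(
            PruneStep(tuple(orig), dropped_orig, res.mae, res.iterations, res.final_ssd, res)
        )
    reductions = {
        f"step{i}->step{i + 1}": reduction_percent(steps[i].mae, steps[i + 1].mae)
        for i in range(len(steps) - 1)
        if steps[i].mae > 0
    }
    if len(steps) > 1 and steps[0].mae > 0:
        reductions["overall"] = reduction_percent(steps[0].mae, steps[-1].mae)
    return CaseReport(steps=tuple(steps), reductions=reductions)
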