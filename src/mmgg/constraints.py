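"""Sampling ground-truth pairwise constraints from a planted partition.

The constraint budget is expressed as a fraction of **all** N(N-1)/2
node pairs, whichever sampling mode is used, so must-link-only,
cannot-link-only and mixed budgets are directly comparable.  Sampled
constraints are noiseless: each pair's label is read off the ground
truth, so a pair is must-link exactly when its nodes share a planted
community.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ConstraintSet, Partition

__all__ = ["ConstraintBudget", "sample_constraints", "BudgetError"]

MODES = ("ml_only", "cl_only", "both")


class BudgetError(ValueError):
    """More constraints requested than pairs of the requested type exist."""


@dataclass(frozen=True)
class ConstraintBudget:
    """How many constraints to draw and of which kind.

    ``fraction`` is relative to all N(N-1)/2 unordered node pairs;
    ``mode`` restricts the candidate pool (``ml_only``: same-community
    pairs, ``cl_only``: different-community pairs, ``both``: all pairs).
    """

    fraction: float
    mode: str = "both"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must lie in [0, 1], got {self.fraction}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    def n_pairs(self, n_nodes: int) -> int:
        return int(round(self.fraction * n_nodes * (n_nodes - 1) / 2))


def sample_constraints(partition: Partition, budget: ConstraintBudget) -> ConstraintSet:
    """Draw constraints uniformly without replacement, labeled by ground truth.

    In ``both`` mode the sample is drawn from all pairs and each pair is
    labeled must-link or cannot-link according to the partition; in
    ``ml_only`` (``cl_only``) mode only same-community (different-
    community) pairs are candidates.
    """
    n = partition.n_nodes
    count = budget.n_pairs(n)
    if count == 0:
        return ConstraintSet.empty()
    iu, ju = np.triu_indices(n, k=1)
    same = partition.labels[iu] == partition.labels[ju]
    if budget.mode == "ml_only":
        pool = np.flatnonzero(same)
    elif budget.mode == "cl_only":
        pool = np.flatnonzero(~same)
    else:
        pool = np.arange(iu.size)
    if count > pool.size:
        raise BudgetError(
            f"requested {count} {budget.mode} constraints but only "
            f"{pool.size} candidate pairs exist"
        )
    rng = np.random.default_rng(budget.seed)
    chosen = rng.choice(pool, size=count, replace=False)
    is_ml = same[chosen]
    ml = frozenset(zip(iu[chosen[is_ml]].tolist(), ju[chosen[is_ml]].tolist()))
    cl = frozenset(zip(iu[chosen[~is_ml]].tolist(), ju[chosen[~is_ml]].tolist()))
    return ConstraintSet(ml, cl)
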