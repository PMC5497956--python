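"""Partition agreement via normalized mutual information (NMI).

Uses the confusion-matrix form with arithmetic normalization and
natural logarithms:

    NMI(T, P) = -2 * sum_ab N_ab log(N_ab N / (N_a N_b))
                / ( sum_a N_a log(N_a / N) + sum_b N_b log(N_b / N) ),

where N_ab counts nodes placed in community a by T and b by P.  NMI is
1 for identical partitions up to relabeling and 0 for independent ones;
0 log 0 is taken as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Partition, ValidationError

__all__ = ["Score", "nmi"]


@dataclass(frozen=True)
class Score:
    nmi: float
    n_nodes: int

    def __post_init__(self) -> None:
        if not -1e-9 <= self.nmi <= 1 + 1e-9:
            raise ValidationError(f"nmi out of [0, 1]: {self.nmi}")


def _contingency(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    _, ti = np.unique(truth, return_inverse=True)
    _, pi = np.unique(pred, return_inverse=True)
    table = np.zeros((ti.max() + 1, pi.max() + 1))
    np.add.at(table, (ti, pi), 1)
    return table


def nmi(truth: Partition, predicted: Partition) -> Score:
    """Normalized mutual information between two partitions of the same nodes."""
    if truth.n_nodes != predicted.n_nodes:
        raise ValidationError(
            f"partition sizes differ: {truth.n_nodes} vs {predicted.n_nodes}"
        )
    n = truth.n_nodes
    if n == 0:
        raise ValidationError("cannot score empty partitions")
    table = _contingency(truth.labels, predicted.labels)
    na = table.sum(axis=1)
    nb = table.sum(axis=0)
    nz = table > 0
    info = (table[nz] * np.log(table[nz] * n / np.outer(na, nb)[nz])).sum()
    denom = (na * np.log(na / n)).sum() + (nb * np.log(nb / n)).sum()
    if denom == 0.0:
        # both partitions are single communities: identical by construction
        value = 1.0
    else:
        value = -2.0 * info / denom
    return Score(nmi=float(np.clip(value, 0.0, 1.0)), n_nodes=n)
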