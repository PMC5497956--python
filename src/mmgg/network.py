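"""Core data containers: networks, pairwise constraint sets, and partitions.

All containers use 0-based node indices internally.  External node
identifiers (strings or integers from input files) are preserved on the
:class:`Network` and re-emitted on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Network", "ConstraintSet", "Partition", "ValidationError"]


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


def canonical_pair(i: int, j: int) -> tuple[int, int]:
    """Return the unordered pair (i, j) in i < j form."""
    if i == j:
        raise ValidationError(f"pair ({i}, {j}) links a node to itself")
    return (i, j) if i < j else (j, i)


@dataclass
class Network:
    """An undirected, unweighted, simple graph held as a dense adjacency matrix.

    Parameters
    ----------
    adjacency
        Symmetric N x N binary matrix with a zero diagonal.
    node_ids
        External identifiers, one per node, in index order.  Defaults to
        the string form of the indices.
    """

    adjacency: np.ndarray
    node_ids: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError(f"adjacency must be square, got shape {a.shape}")
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValidationError("adjacency diagonal must be zero (no self-loops)")
        vals = np.unique(a)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.float64)
        if self.node_ids is None:
            self.node_ids = [str(i) for i in range(a.shape[0])]
        if len(self.node_ids) != a.shape[0]:
            raise ValidationError("node_ids length must equal the number of nodes")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(round(self.adjacency.sum() / 2))

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edges(self) -> list[tuple[int, int]]:
        """All edges as (i, j) index pairs with i < j."""
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(iu.tolist(), ju.tolist()))

    @classmethod
    def from_edges(
        cls, n_nodes: int, edges: Iterable[tuple[int, int]], node_ids: list | None = None
    ) -> "Network":
        a = np.zeros((n_nodes, n_nodes))
        for i, j in edges:
            if i == j:
                continue
            a[i, j] = a[j, i] = 1.0
        return cls(a, node_ids)


@dataclass
class ConstraintSet:
    """Disjoint sets of must-link and cannot-link node-index pairs.

    Pairs are stored in canonical (i < j) form.  A pair may appear in at
    most one of the two sets: prior knowledge cannot simultaneously assert
    that two nodes share a community and that they do not.
    """

    must_link: frozenset = frozenset()
    cannot_link: frozenset = frozenset()

    def __post_init__(self) -> None:
        ml = frozenset(canonical_pair(*p) for p in self.must_link)
        cl = frozenset(canonical_pair(*p) for p in self.cannot_link)
        clash = ml & cl
        if clash:
            raise ValidationError(
                f"{len(clash)} pair(s) listed as both must-link and cannot-link, "
                f"e.g. {sorted(clash)[0]}"
            )
        self.must_link = ml
        self.cannot_link = cl

    @property
    def size(self) -> int:
        """Total number of constraints P = |ML| + |CL|."""
        return len(self.must_link) + len(self.cannot_link)

    def validate_indices(self, n_nodes: int) -> None:
        for i, j in list(self.must_link) + list(self.cannot_link):
            if not (0 <= i < n_nodes and 0 <= j < n_nodes):
                raise ValidationError(
                    f"constraint pair ({i}, {j}) outside node range [0, {n_nodes})"
                )

    @classmethod
    def empty(cls) -> "ConstraintSet":
        return cls(frozenset(), frozenset())


@dataclass
class Partition:
    """A hard assignment of every node to one of K communities.

    Labels are 1-based community indices in 1..K; K is declared so that
    empty communities are representable.
    """

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if lab.ndim != 1:
            raise ValidationError("labels must be a 1-d vector")
        if lab.size and (lab.min() < 1 or lab.max() > self.k):
            raise ValidationError(
                f"labels must lie in 1..{self.k}, got range "
                f"[{lab.min()}, {lab.max()}]"
            )
        self.labels = lab

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    @property
    def sizes(self) -> np.ndarray:
        """Community sizes, index c holds the size of community c+1."""
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def communities(self) -> list[np.ndarray]:
        """Node index arrays per community, empty communities included."""
        return [np.flatnonzero(self.labels == c) for c in range(1, self.k + 1)]

    @classmethod
    def from_labels(cls, labels: Sequence[int]) -> "Partition":
        lab = np.asarray(labels, dtype=int)
        return cls(lab, int(lab.max()) if lab.size else 0)
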