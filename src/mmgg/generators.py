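"""Synthetic benchmark networks with planted community structure.

Two families are provided:

* **GN** — the classic four-community benchmark: 128 nodes in four
  equal communities of 32, expected node degree 16 split into ``z_in``
  intra-community and ``z_out`` inter-community neighbours
  (``z_in + z_out = 16``).  Implemented as a planted-partition
  (stochastic block) model with intra/inter edge probabilities chosen to
  hit those expected degrees.

* **LFR** — heterogeneous benchmark whose node degrees and community
  sizes follow truncated power laws; the mixing parameter ``mu`` is the
  expected fraction of each node's edges that leave its community.
  Construction: sample a degree sequence and community sizes, assign
  nodes to communities so each node's internal degree fits
  (``(1-mu)*deg <= size - 1``), wire intra- and inter-community stubs by
  the configuration model, then repair self-loops, duplicate edges and
  misplaced inter-community edges by degree-preserving rewiring.

Both generators are fully determined by their ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import Network, Partition

__all__ = [
    "GNParams",
    "LFRParams",
    "generate_gn",
    "generate_lfr",
    "mixing_fraction",
    "GenerationError",
]


class GenerationError(RuntimeError):
    """The requested benchmark could not be realized."""


@dataclass(frozen=True)
class GNParams:
    """Settings for the four-community GN benchmark.

    ``z_out`` is the expected number of inter-community neighbours per
    node; ``z_in = total_degree - z_out`` is the expected intra-community
    degree.
    """

    z_out: float
    total_degree: int = 16
    n_communities: int = 4
    community_size: int = 32
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.z_out <= self.total_degree:
            raise ValueError(
                f"z_out must lie in [0, {self.total_degree}], got {self.z_out}"
            )

    @property
    def z_in(self) -> float:
        return self.total_degree - self.z_out

    @property
    def n_nodes(self) -> int:
        return self.n_communities * self.community_size


def generate_gn(params: GNParams) -> tuple[Network, Partition]:
    """Sample a GN benchmark network and its planted 4-way partition.

    Each intra-community pair is connected independently with probability
    ``z_in / (community_size - 1)`` and each inter-community pair with
    ``z_out / (n_nodes - community_size)``, so the expected intra- and
    inter-community degrees equal ``z_in`` and ``z_out``.
    """
    n = params.n_nodes
    labels = np.repeat(np.arange(1, params.n_communities + 1), params.community_size)
    p_in = params.z_in / (params.community_size - 1)
    p_out = params.z_out / (n - params.community_size)
    rng = np.random.default_rng(params.seed)
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    p = np.where(same, p_in, p_out)
    hit = rng.random(iu.size) < p
    a = np.zeros((n, n))
    a[iu[hit], ju[hit]] = 1.0
    a += a.T
    return Network(a), Partition(labels, params.n_communities)


@dataclass(frozen=True)
class LFRParams:
    """Settings for the LFR benchmark.

    ``tau_degree`` and ``tau_community`` are the (positive) exponents of
    the decaying power laws ``p(k) ~ k**(-tau)`` for node degree and
    community size.  ``avg_degree`` fixes the mean of the degree
    distribution by solving for its lower cutoff; ``max_degree`` caps it.
    """

    n_nodes: int = 1000
    mu: float = 0.5
    tau_degree: float = 2.0
    tau_community: float = 1.0
    min_community: int = 10
    max_community: int = 50
    avg_degree: float = 20.0
    max_degree: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if not self.min_community <= self.max_community <= self.n_nodes:
            raise ValueError("need min_community <= max_community <= n_nodes")


def _powerlaw_sample(
    rng: np.random.Generator, tau: float, lo: int, hi: int, size: int
) -> np.ndarray:
    """Draw integers in [lo, hi] with probability proportional to k**(-tau)."""
    support = np.arange(lo, hi + 1)
    p = support.astype(float) ** (-tau)
    p /= p.sum()
    return rng.choice(support, size=size, p=p)


def _degree_cutoff(tau: float, hi: int, target_mean: float) -> int:
    """Lower cutoff of the discrete power law whose mean best matches target_mean."""
    best, best_err = 1, math.inf
    for lo in range(1, hi + 1):
        k = np.arange(lo, hi + 1, dtype=float)
        w = k ** (-tau)
        mean = (k * w).sum() / w.sum()
        err = abs(mean - target_mean)
        if err < best_err:
            best, best_err = lo, err
    return best


def _sample_community_sizes(rng: np.random.Generator, params: LFRParams) -> np.ndarray:
    """Community sizes summing exactly to n_nodes, each in [min, max]_community."""
    for _ in range(1000):
        sizes: list[int] = []
        total = 0
        while total < params.n_nodes:
            s = int(
                _powerlaw_sample(
                    rng, params.tau_community, params.min_community,
                    params.max_community, 1,
                )[0]
            )
            sizes.append(s)
            total += s
        if total == params.n_nodes:
            return np.asarray(sizes)
    raise GenerationError(
        f"could not partition {params.n_nodes} nodes into community sizes in "
        f"[{params.min_community}, {params.max_community}] after 1000 attempts"
    )


def _assign_nodes(
    rng: np.random.Generator,
    sizes: np.ndarray,
    internal_deg: np.ndarray,
) -> np.ndarray:
    """Place each node in a community with size - 1 >= its internal degree.

    Nodes are placed in decreasing internal-degree order into a random
    feasible community with free capacity; when every feasible community
    is full, the node swaps in for a strictly smaller-degree member,
    which guarantees termination.
    """
    import heapq

    n = internal_deg.size
    n_comm = sizes.size
    membership = np.full(n, -1)
    members: list[list[int]] = [[] for _ in range(n_comm)]
    # max-heap on internal degree, random tie-break
    heap = [(-internal_deg[i], rng.random(), i) for i in range(n)]
    heapq.heapify(heap)
    while heap:
        _, _, node = heapq.heappop(heap)
        d = internal_deg[node]
        feasible = np.flatnonzero(sizes - 1 >= d)
        if feasible.size == 0:
            raise GenerationError(
                f"no community large enough for internal degree {d}"
            )
        free = feasible[[len(members[c]) < sizes[c] for c in feasible]]
        if free.size:
            c = int(rng.choice(free))
        else:
            swaps = []
            for c in feasible:
                weakest = min(members[c], key=lambda m: internal_deg[m])
                if internal_deg[weakest] < d:
                    swaps.append((c, weakest))
            if not swaps:
                raise GenerationError(
                    "community capacities cannot accommodate the internal degrees"
                )
            c, out = swaps[int(rng.integers(len(swaps)))]
            members[c].remove(out)
            membership[out] = -1
            heapq.heappush(heap, (-internal_deg[out], rng.random(), out))
        members[c].append(node)
        membership[node] = c
    return membership


def _repair_internal_degrees(
    sizes: np.ndarray, internal: np.ndarray
) -> np.ndarray:
    """Trim internal degrees so every node can be housed.

    Nodes with internal degree >= d only fit communities of size > d;
    whenever the number of such nodes exceeds the slots those
    communities offer, the largest internal degrees are reduced to
    d - 1.  Returns the adjusted copy.
    """
    internal = internal.copy()
    for d in range(int(internal.max()), 0, -1):
        slots = int(sizes[sizes >= d + 1].sum())
        over = np.flatnonzero(internal >= d)
        excess = over.size - slots
        if excess > 0:
            # lower the largest degrees first
            order = over[np.argsort(internal[over])][::-1]
            internal[order[:excess]] = d - 1
    return internal


def _pair_stubs(
    rng: np.random.Generator,
    stubs: np.ndarray,
    edge_set: set[tuple[int, int]],
    same_community_ok: bool,
    membership: np.ndarray,
    max_attempts: int,
) -> list[tuple[int, int]]:
    """Configuration-model pairing with rewiring of invalid pairs.

    A pair is invalid if it is a self-loop, duplicates an existing edge,
    or (for inter-community wiring) falls inside one community.  Invalid
    pairs are repaired by swapping endpoints with a random accepted edge;
    irreparable pairs are dropped.
    """
    stubs = rng.permutation(stubs)
    if stubs.size % 2:
        stubs = stubs[:-1]
    proposed = list(zip(stubs[0::2].tolist(), stubs[1::2].tolist()))

    def ok(u: int, v: int) -> bool:
        if u == v:
            return False
        key = (u, v) if u < v else (v, u)
        if key in edge_set:
            return False
        if not same_community_ok and membership[u] == membership[v]:
            return False
        return True

    accepted: list[tuple[int, int]] = []
    bad: list[tuple[int, int]] = []
    for u, v in proposed:
        if ok(u, v):
            accepted.append((u, v))
            edge_set.add((u, v) if u < v else (v, u))
        else:
            bad.append((u, v))
    attempts = 0
    while bad and attempts < max_attempts:
        attempts += 1
        u, v = bad.pop()
        if ok(u, v):
            accepted.append((u, v))
            edge_set.add((u, v) if u < v else (v, u))
            continue
        if not accepted:
            continue  # drop
        idx = int(rng.integers(len(accepted)))
        x, y = accepted[idx]
        if rng.random() < 0.5:
            x, y = y, x
        # propose swap (u,v),(x,y) -> (u,x),(v,y)
        key_xy = (x, y) if x < y else (y, x)
        edge_set.discard(key_xy)
        if ok(u, x) and ok(v, y) and {u, x} != {v, y}:
            accepted[idx] = (u, x)
            edge_set.add((u, x) if u < x else (x, u))
            accepted.append((v, y))
            edge_set.add((v, y) if v < y else (y, v))
        else:
            edge_set.add(key_xy)
            bad.insert(0, (u, v))
    return accepted


def generate_lfr(params: LFRParams) -> tuple[Network, Partition]:
    """Sample an LFR benchmark network and its planted partition."""
    rng = np.random.default_rng(params.seed)
    k_min = _degree_cutoff(params.tau_degree, params.max_degree, params.avg_degree)
    degrees = _powerlaw_sample(
        rng, params.tau_degree, k_min, params.max_degree, params.n_nodes
    ).astype(int)

    membership = None
    for attempt in range(5):
        sizes = _sample_community_sizes(rng, params)
        internal = np.rint((1.0 - params.mu) * degrees).astype(int)
        internal = np.minimum(internal, sizes.max() - 1)
        internal = _repair_internal_degrees(sizes, internal)
        try:
            membership = _assign_nodes(rng, sizes, internal)
            break
        except GenerationError:
            if attempt == 4:
                raise
    if params.mu == 0.0:
        degrees = internal.copy()  # no external stubs at zero mixing

    # parity fixes: each community's internal stub count and the global
    # external stub count must be even
    external = degrees - internal
    for c in range(sizes.size):
        nodes_c = np.flatnonzero(membership == c)
        if internal[nodes_c].sum() % 2:
            cand = nodes_c[internal[nodes_c] > 0]
            node = int(rng.choice(cand))
            internal[node] -= 1
            if params.mu == 0.0:
                degrees[node] -= 1
            else:
                external[node] += 1
    external = degrees - internal
    if external.sum() % 2:
        cand = np.flatnonzero(external > 0)
        node = int(rng.choice(cand))
        external[node] -= 1
        degrees[node] -= 1

    edge_set: set[tuple[int, int]] = set()
    edges: list[tuple[int, int]] = []
    budget = 10 * max(1, int(degrees.sum() // 2))
    for c in range(sizes.size):
        nodes_c = np.flatnonzero(membership == c)
        stubs = np.repeat(nodes_c, internal[nodes_c])
        edges.extend(
            _pair_stubs(rng, stubs, edge_set, True, membership, budget)
        )
    ext_stubs = np.repeat(np.arange(params.n_nodes), external)
    edges.extend(
        _pair_stubs(rng, ext_stubs, edge_set, False, membership, budget)
    )

    net = Network.from_edges(params.n_nodes, edges)
    part = Partition(membership + 1, sizes.size)
    return net, part


def mixing_fraction(network: Network, partition: Partition) -> float:
    """Mean over nodes of the fraction of incident edges leaving the node's community."""
    a = network.adjacency
    same = partition.labels[:, None] == partition.labels[None, :]
    deg = a.sum(axis=1)
    ext = (a * ~same).sum(axis=1)
    nz = deg > 0
    return float((ext[nz] / deg[nz]).mean())
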