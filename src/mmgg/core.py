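"""Multi-variance Gaussian encoding of topology + constraints, and the
weighted symmetric NMF solver.

Model
-----
Each node pair (i, j) is assumed to generate its observation —
edge/non-edge, must-link, or cannot-link — from a Gaussian centred on
the membership similarity ``x_i @ x_j`` with a pair-specific variance
reflecting the confidence of the information source:

==============================  ==========  ================
pair group                      mean o_ij   variance
==============================  ==========  ================
must-link (edge or not)         1           sigma2_ml
cannot-link (edge or not)       0           sigma2_cl
unconstrained edge              1           sigma2_adj
unconstrained non-edge          0           sigma2_adj
==============================  ==========  ================

Maximizing the joint likelihood over nonnegative memberships X is the
weighted symmetric NMF problem

    min_{X >= 0}  || W (.) (X X^T - O) ||_F^2,

solved by the damped multiplicative update

    X_ik <- X_ik * ( ((W^2 (.) O) X)_ik / ((W^2 (.) X X^T) X)_ik )^(1/4),

which never increases the objective and preserves nonnegativity.
Weights are kept on a relative scale: unconstrained pairs have weight 1
and constrained pairs ``sigma2_adj / sigma2_ml`` (or ``_cl``), since
only the weight ratios matter to the update.  Self-pairs carry no
information, so diagonal weights are 0.

Implementation note: because all but the P constrained entries of W
equal the base weight, W is stored as that scalar plus a sparse list of
corrections, and each update costs O((M + P) K + N K^2) instead of
O(N^2 K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np
import scipy.sparse as sp

from .network import ConstraintSet, Network, Partition, ValidationError

__all__ = [
    "VariancePlan",
    "WeightedTarget",
    "SolverConfig",
    "FactorizationResult",
    "build_weighted_target",
    "mmgg_loss",
    "update_step",
    "factorize",
    "assign_communities",
]


@dataclass(frozen=True)
class VariancePlan:
    """Variances of the three Gaussian information channels.

    Defaults follow the tuned operating point ``sigma2_adj = 1``,
    ``sigma2_ml = 0.2``, ``sigma2_cl = 0.1``, i.e. relative weights of 5
    for must-link and 10 for cannot-link entries.
    """

    sigma2_adj: float = 1.0
    sigma2_ml: float = 0.2
    sigma2_cl: float = 0.1

    def __post_init__(self) -> None:
        for name in ("sigma2_adj", "sigma2_ml", "sigma2_cl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def ml_weight(self) -> float:
        """Relative weight of must-link entries, sigma2_adj / sigma2_ml."""
        return self.sigma2_adj / self.sigma2_ml

    @property
    def cl_weight(self) -> float:
        """Relative weight of cannot-link entries, sigma2_adj / sigma2_cl."""
        return self.sigma2_adj / self.sigma2_cl


class WeightedTarget:
    """The (W, O) pair defining a weighted symmetric NMF problem.

    ``O`` is the dense symmetric 0/1 target similarity matrix.  ``W`` is
    represented as a scalar ``base_weight`` for every off-diagonal pair
    plus per-entry overrides on the (few) constrained pairs; diagonal
    weights are always 0.  Dense ``weights`` are materialized on demand.
    """

    def __init__(
        self,
        target: np.ndarray,
        base_weight: float = 1.0,
        corr_rows: np.ndarray | None = None,
        corr_cols: np.ndarray | None = None,
        corr_weights: np.ndarray | None = None,
    ) -> None:
        target = np.asarray(target, dtype=np.float64)
        if target.ndim != 2 or target.shape[0] != target.shape[1]:
            raise ValidationError("target must be a square matrix")
        if not np.array_equal(target, target.T):
            raise ValidationError("target must be symmetric")
        if not np.all(np.isin(np.unique(target), (0.0, 1.0))):
            raise ValidationError("target entries must be 0 or 1")
        self.target = target
        self.base_weight = float(base_weight)
        self.corr_rows = (
            np.asarray(corr_rows, dtype=np.intp)
            if corr_rows is not None
            else np.empty(0, dtype=np.intp)
        )
        self.corr_cols = (
            np.asarray(corr_cols, dtype=np.intp)
            if corr_cols is not None
            else np.empty(0, dtype=np.intp)
        )
        self.corr_weights = (
            np.asarray(corr_weights, dtype=np.float64)
            if corr_weights is not None
            else np.empty(0)
        )
        if not (
            self.corr_rows.shape == self.corr_cols.shape == self.corr_weights.shape
        ):
            raise ValidationError("correction arrays must have matching shapes")
        if np.any(self.corr_rows == self.corr_cols):
            raise ValidationError("weight corrections must be off-diagonal")
        np.fill_diagonal(self.target, 0.0)
        self._cache: dict | None = None

    @property
    def n_nodes(self) -> int:
        return self.target.shape[0]

    @property
    def n_corrections(self) -> int:
        """Number of stored weight overrides (2P for P constrained pairs)."""
        return self.corr_rows.size

    @property
    def weights(self) -> np.ndarray:
        """Dense weight matrix W (materialized; for inspection and small problems)."""
        n = self.n_nodes
        w = np.full((n, n), self.base_weight)
        np.fill_diagonal(w, 0.0)
        w[self.corr_rows, self.corr_cols] = self.corr_weights
        return w

    def scaled(self, c: float) -> "WeightedTarget":
        """A copy with every weight multiplied by ``c`` (same target O)."""
        return WeightedTarget(
            self.target.copy(),
            self.base_weight * c,
            self.corr_rows.copy(),
            self.corr_cols.copy(),
            self.corr_weights * c,
        )

    @classmethod
    def from_dense(cls, weights: np.ndarray, target: np.ndarray) -> "WeightedTarget":
        """Build from explicit dense W and O (every off-diagonal entry stored)."""
        weights = np.asarray(weights, dtype=np.float64)
        if not np.array_equal(weights, weights.T):
            raise ValidationError("weights must be symmetric")
        if np.any(weights < 0):
            raise ValidationError("weights must be nonnegative")
        n = weights.shape[0]
        rows, cols = np.nonzero(~np.eye(n, dtype=bool) & (weights != 0))
        return cls(target, 0.0, rows, cols, weights[rows, cols])

    # -- cached structures for the fast update/loss path ------------------

    def _ops(self) -> dict:
        if self._cache is None:
            n = self.n_nodes
            wsq_o = self.target.copy()  # base weight contributes base^2 * O
            wsq_o *= self.base_weight**2
            wsq_o[self.corr_rows, self.corr_cols] = (
                self.corr_weights**2 * self.target[self.corr_rows, self.corr_cols]
            )
            num_csr = sp.csr_matrix(wsq_o)
            o_rows, o_cols = np.nonzero(self.target)
            oe_rows, oe_cols = np.nonzero(np.triu(self.target, k=1))
            corr_csr = None
            slot_to_pair = None
            u_rows = u_cols = u_delta = u_o = None
            if self.n_corrections:
                coo = sp.coo_matrix(
                    (
                        np.arange(1, self.n_corrections + 1, dtype=np.float64),
                        (self.corr_rows, self.corr_cols),
                    ),
                    shape=(n, n),
                )
                corr_csr = coo.tocsr()
                perm = corr_csr.data.astype(np.intp) - 1
                # unordered-pair view: both orientations of a constrained
                # pair share one reconstruction x_i . x_j
                lo = np.minimum(self.corr_rows, self.corr_cols)
                hi = np.maximum(self.corr_rows, self.corr_cols)
                keys = lo * n + hi
                u_keys, first = np.unique(keys, return_index=True)
                u_rows, u_cols = lo[first], hi[first]
                u_delta = (self.corr_weights**2 - self.base_weight**2)[first]
                u_o = self.target[u_rows, u_cols]
                pair_id = np.searchsorted(u_keys, keys)
                slot_to_pair = pair_id[perm]
            self._cache = {
                "num_csr": num_csr,
                "o_rows": o_rows,
                "o_cols": o_cols,
                "oe_rows": oe_rows,
                "oe_cols": oe_cols,
                "corr_csr": corr_csr,
                "slot_to_pair": slot_to_pair,
                "u_rows": u_rows,
                "u_cols": u_cols,
                "u_delta": u_delta,
                "u_o": u_o,
                "corr_o": self.target[self.corr_rows, self.corr_cols],
                "corr_wsq_delta": self.corr_weights**2 - self.base_weight**2,
            }
        return self._cache


@dataclass(frozen=True)
class SolverConfig:
    """Multi-restart solver settings.

    Convergence stops a restart when the loss difference between two
    consecutive iterations falls below ``tol`` (absolute by default; set
    ``relative=True`` to scale by the current loss).
    """

    n_restarts: int = 20
    max_iter: int = 1000
    tol: float = 1e-3
    eps: float = 1e-12
    relative: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_restarts < 1 or self.max_iter < 1 or self.tol <= 0:
            raise ValueError("need n_restarts >= 1, max_iter >= 1, tol > 0")


@dataclass
class FactorizationResult:
    """Outcome of a multi-restart factorization."""

    membership: np.ndarray
    loss: float
    iterations: list[int] = field(default_factory=list)
    best_restart: int = 0
    converged: list[bool] = field(default_factory=list)


def build_weighted_target(
    network: Network,
    constraints: ConstraintSet,
    variances: VariancePlan | None = None,
    amplify_ml: bool = True,
    amplify_cl: bool = True,
) -> WeightedTarget:
    """Encode topology and constraints as a (W, O) factorization problem.

    The target O equals the adjacency matrix with must-link entries set
    to 1 and cannot-link entries set to 0.  Constrained entries get
    weight ``sigma2_adj / sigma2_ml`` (must-link) or ``sigma2_adj /
    sigma2_cl`` (cannot-link) when the corresponding ``amplify_*`` flag
    is on, and weight 1 otherwise; unconstrained pairs always have
    weight 1.  With both flags off this is exactly the topology-
    modification ("ModTop") encoding.
    """
    variances = variances or VariancePlan()
    constraints.validate_indices(network.n_nodes)
    if amplify_ml and variances.sigma2_ml > variances.sigma2_adj:
        raise ValueError("amplified must-link variance must not exceed sigma2_adj")
    if amplify_cl and variances.sigma2_cl > variances.sigma2_adj:
        raise ValueError("amplified cannot-link variance must not exceed sigma2_adj")

    o = network.adjacency.copy()
    rows: list[int] = []
    cols: list[int] = []
    wvals: list[float] = []

    def apply(pairs, value: float, weight: float | None) -> None:
        for i, j in pairs:
            o[i, j] = o[j, i] = value
            if weight is not None and weight != 1.0:
                rows.extend((i, j))
                cols.extend((j, i))
                wvals.extend((weight, weight))

    apply(
        constraints.must_link, 1.0, variances.ml_weight if amplify_ml else None
    )
    apply(
        constraints.cannot_link, 0.0, variances.cl_weight if amplify_cl else None
    )
    return WeightedTarget(
        o,
        1.0,
        np.asarray(rows, dtype=np.intp),
        np.asarray(cols, dtype=np.intp),
        np.asarray(wvals),
    )


def _check_membership(x: np.ndarray, wt: WeightedTarget) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] != wt.n_nodes:
        raise ValidationError(
            f"membership shape {x.shape} does not match {wt.n_nodes} nodes"
        )
    if np.any(x < 0):
        raise ValidationError("membership entries must be nonnegative")
    return x


def mmgg_loss(x: np.ndarray, wt: WeightedTarget) -> float:
    """Objective ``|| W (.) (X X^T - O) ||_F^2`` (diagonal excluded via W)."""
    x = _check_membership(x, wt)
    ops = wt._ops()
    g = x.T @ x
    row_norms = np.einsum("ik,ik->i", x, x)
    # sum over off-diagonal entries of (X X^T)^2
    sq_offdiag = float((g * g).sum() - (row_norms**2).sum())
    # base-weight part: base^2 * sum_offdiag (XX^T - O)^2
    s_o = float(
        np.einsum("ik,ik->", x[ops["o_rows"]], x[ops["o_cols"]])
    )  # sum of XX^T over nonzero O entries
    n_o = ops["o_rows"].size
    loss = wt.base_weight**2 * (sq_offdiag - 2.0 * s_o + n_o)
    if wt.n_corrections:
        xx = np.einsum("ik,ik->i", x[wt.corr_rows], x[wt.corr_cols])
        res = (xx - ops["corr_o"]) ** 2
        loss += float(ops["corr_wsq_delta"] @ res)
    return max(loss, 0.0)


def update_step(
    x: np.ndarray, wt: WeightedTarget, eps: float = 1e-12
) -> np.ndarray:
    """One damped multiplicative update; nonnegative in, nonnegative out.

    Zero entries of X stay zero; where ``X X^T`` already reconstructs O
    on all positive-weight entries the multiplier is 1 (up to ``eps``).
    """
    x = _check_membership(x, wt)
    ops = wt._ops()
    num = ops["num_csr"] @ x
    g = x.T @ x
    row_norms = np.einsum("ik,ik->i", x, x)
    den = wt.base_weight**2 * (x @ g - row_norms[:, None] * x)
    if wt.n_corrections:
        xx = np.einsum("ik,ik->i", x[ops["u_rows"]], x[ops["u_cols"]])
        ops["corr_csr"].data = (ops["u_delta"] * xx)[ops["slot_to_pair"]]
        den += ops["corr_csr"] @ x
    ratio = num / (den + eps)
    np.power(ratio, 0.25, out=ratio)
    return x * ratio


@numba.njit(cache=False)
def _pair_dots(x: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Reconstruction (X X^T)_ij for an explicit list of (i, j) pairs."""
    out = np.empty(rows.size)
    for p in range(rows.size):
        i, j = rows[p], cols[p]
        s = 0.0
        for k in range(x.shape[1]):
            s += x[i, k] * x[j, k]
        out[p] = s
    return out


def _run_restart(
    x: np.ndarray, wt: WeightedTarget, config: SolverConfig
) -> tuple[np.ndarray, float, int, bool]:
    """Iterate the multiplicative update from one start until convergence.

    Equivalent to alternating :func:`update_step` and :func:`mmgg_loss`;
    the shared intermediates (the K x K Gram matrix, row norms, and the
    constrained-pair reconstructions) are computed once per iteration.
    """
    ops = wt._ops()
    b2 = wt.base_weight**2
    num_csr = ops["num_csr"]
    corr_csr = ops["corr_csr"]
    slot_to_pair = ops["slot_to_pair"]
    u_rows, u_cols = ops["u_rows"], ops["u_cols"]
    u_delta, u_o = ops["u_delta"], ops["u_o"]
    oe_rows, oe_cols = ops["oe_rows"], ops["oe_cols"]
    n_o = ops["o_rows"].size
    has_corr = wt.n_corrections > 0
    eps = config.eps

    def state(x: np.ndarray):
        g = x.T @ x
        row_norms = np.einsum("ik,ik->i", x, x)
        xx = _pair_dots(x, u_rows, u_cols) if has_corr else None
        sq_offdiag = float((g * g).sum() - (row_norms**2).sum())
        s_o = 2.0 * float(_pair_dots(x, oe_rows, oe_cols).sum())
        loss = b2 * (sq_offdiag - 2.0 * s_o + n_o)
        if xx is not None:
            loss += 2.0 * float(u_delta @ (xx - u_o) ** 2)
        return g, row_norms, xx, max(loss, 0.0)

    g, row_norms, xx, loss_prev = state(x)
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        num = num_csr @ x
        den = b2 * (x @ g - row_norms[:, None] * x)
        if xx is not None:
            corr_csr.data = (u_delta * xx)[slot_to_pair]
            den += corr_csr @ x
        ratio = num / (den + eps)
        np.power(ratio, 0.25, out=ratio)
        x = x * ratio
        g, row_norms, xx, loss = state(x)
        gap = abs(loss_prev - loss)
        if config.relative and loss_prev > 0:
            gap /= loss_prev
        loss_prev = loss
        if gap < config.tol:
            return x, loss, n_iter, True
    return x, loss_prev, n_iter, False


def factorize(
    wt: WeightedTarget, k: int, config: SolverConfig | None = None
) -> FactorizationResult:
    """Minimize the weighted objective from ``n_restarts`` random starts.

    Each restart draws X uniformly from (0, 1), iterates the
    multiplicative update until the loss change drops below ``tol`` or
    ``max_iter`` is reached, and the restart with the smallest final
    loss wins.
    """
    config = config or SolverConfig()
    n = wt.n_nodes
    if k < 1 or k > n:
        raise ValueError(f"community count k={k} must lie in [1, {n}]")
    rng = np.random.default_rng(config.seed)
    best_x: np.ndarray | None = None
    best_loss = np.inf
    best_restart = 0
    iterations: list[int] = []
    converged: list[bool] = []
    for r in range(config.n_restarts):
        x0 = rng.uniform(size=(n, k))
        x, loss, n_iter, conv = _run_restart(x0, wt, config)
        iterations.append(n_iter)
        converged.append(conv)
        if loss < best_loss:
            best_loss = loss
            best_x = x
            best_restart = r
    assert best_x is not None
    return FactorizationResult(
        membership=best_x,
        loss=mmgg_loss(best_x, wt),  # canonical evaluation of the winner
        iterations=iterations,
        best_restart=best_restart,
        converged=converged,
    )


class AssignmentError(RuntimeError):
    """A node has no community affinity (all-zero membership row)."""


def assign_communities(result: FactorizationResult) -> Partition:
    """Hard labels: argmax over communities, ties toward the smaller index."""
    x = result.membership
    zero_rows = np.flatnonzero(~x.any(axis=1))
    if zero_rows.size:
        raise AssignmentError(
            f"node(s) {zero_rows[:5].tolist()} have all-zero membership rows"
        )
    return Partition(np.argmax(x, axis=1) + 1, x.shape[1])
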