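"""Benchmark sweeps: NMI versus constraint budget per method variant,
and the variance-grid tuning surface.

Replication and seeding
-----------------------
Every cell of a sweep (one network replicate x one constraint draw) gets
child seeds derived by hashing ``(master_seed, purpose, indices)``, so
cells are mutually independent: removing a variant, fraction, or grid
point from the configuration does not change any other cell's numbers.
The solver seed is shared across variants within a cell, so variant
comparisons are paired, and at a zero constraint budget every variant
reproduces the unsupervised factorization exactly.

Constraint protocol
-------------------
At budget fraction ``f`` one uniform sample of ``round(f * N(N-1)/2)``
node pairs is drawn per (network, draw) cell and labeled from the
planted partition; every variant sees the same labeled sample and uses
the subset of constraint types it encodes.  Must-link-only variants
therefore receive the same-community pairs of the sample (roughly the
same-community pair fraction of it), not ``f`` of all pairs as
must-links — the budget measures supervision inspected, not
constraints of each type.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .baselines import VARIANTS, MethodVariant, run_variant
from .constraints import BudgetError, ConstraintBudget, sample_constraints
from .core import SolverConfig, VariancePlan
from .evaluation import nmi
from .generators import GNParams, LFRParams, generate_gn, generate_lfr
from .network import ConstraintSet

__all__ = ["SweepConfig", "run_sweep", "run_variance_grid", "derive_seed", "summarize"]


def derive_seed(master_seed: int, *parts) -> int:
    """Deterministic child seed < 2**31 from a master seed and a label path."""
    key = "|".join([str(master_seed), *map(str, parts)])
    digest = hashlib.blake2s(key.encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


@dataclass
class SweepConfig:
    """Full description of a benchmark sweep.

    ``generator`` carries the network family and its parameters (the
    seed field inside it is ignored; per-replicate seeds are derived
    from ``seed``).  ``variance_grid`` lists (1/sigma2_ml, 1/sigma2_cl)
    amplification pairs for :func:`run_variance_grid`.
    """

    generator: GNParams | LFRParams
    fractions: Sequence[float] = (0.03,)
    variants: Sequence[MethodVariant | str] = (MethodVariant.MMGG_MCL,)
    n_networks: int = 10
    n_constraint_draws: int = 1
    variances: VariancePlan = field(default_factory=VariancePlan)
    variance_grid: Sequence[tuple[float, float]] | None = None
    solver: SolverConfig = field(default_factory=SolverConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fractions or not self.variants:
            raise ValueError("fractions and variants must be nonempty")
        if self.n_networks < 1 or self.n_constraint_draws < 1:
            raise ValueError("replicate counts must be >= 1")
        self.variants = [MethodVariant(v) for v in self.variants]

    def to_metadata(self) -> dict:
        meta = {
            "generator": {"family": type(self.generator).__name__, **asdict(self.generator)},
            "fractions": list(self.fractions),
            "variants": [v.value for v in self.variants],
            "n_networks": self.n_networks,
            "n_constraint_draws": self.n_constraint_draws,
            "variances": asdict(self.variances),
            "variance_grid": [list(g) for g in self.variance_grid] if self.variance_grid else None,
            "solver": asdict(self.solver),
            "seed": self.seed,
        }
        return meta


def _generate(config: SweepConfig, net_rep: int):
    seed = derive_seed(config.seed, "network", net_rep)
    gen = replace(config.generator, seed=seed)
    if isinstance(gen, GNParams):
        return generate_gn(gen)
    return generate_lfr(gen)


def _cell(
    config: SweepConfig,
    network,
    truth,
    variant: MethodVariant,
    fraction: float,
    net_rep: int,
    draw_rep: int,
    variances: VariancePlan,
) -> dict:
    spec = VARIANTS[variant]
    con_seed = derive_seed(config.seed, "constraints", net_rep, draw_rep, fraction)
    solve_seed = derive_seed(config.seed, "solver", net_rep, draw_rep)
    row = {
        "variant": variant.value,
        "fraction": fraction,
        "network_rep": net_rep,
        "draw_rep": draw_rep,
        "network_seed": derive_seed(config.seed, "network", net_rep),
        "constraint_seed": con_seed,
        "solver_seed": solve_seed,
    }
    try:
        if fraction == 0.0 or not spec.needs_constraints:
            constraints = ConstraintSet.empty()
            run_as = MethodVariant.SNMF  # empty-budget degeneracy
        else:
            constraints = sample_constraints(
                truth, ConstraintBudget(fraction, "both", seed=con_seed)
            )
            run_as = variant
        part, result = run_variant(
            network,
            constraints,
            truth.k,
            run_as,
            variances,
            replace(config.solver, seed=solve_seed),
        )
    except BudgetError as exc:
        row.update({"nmi": float("nan"), "loss": float("nan"),
                    "iterations": 0, "error": str(exc)})
        return row
    row.update(
        {
            "nmi": nmi(truth, part).nmi,
            "loss": result.loss,
            "iterations": int(sum(result.iterations)),
            "error": "",
        }
    )
    return row


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """NMI of every (variant, fraction) cell across replicates, long format."""
    rows = []
    for net_rep in range(config.n_networks):
        network, truth = _generate(config, net_rep)
        for draw_rep in range(config.n_constraint_draws):
            for variant in config.variants:
                for fraction in config.fractions:
                    rows.append(
                        _cell(
                            config, network, truth, variant, fraction,
                            net_rep, draw_rep, config.variances,
                        )
                    )
    return pd.DataFrame(rows)


def run_variance_grid(config: SweepConfig) -> pd.DataFrame:
    """NMI surface over (1/sigma2_ml, 1/sigma2_cl) amplification pairs.

    Runs the fully weighted both-constraint variant at each grid point
    and the first fraction in ``config.fractions``; the (1, 1) corner is
    the unit-weight (topology-modification) special case.
    """
    if not config.variance_grid:
        raise ValueError("config.variance_grid must be supplied")
    fraction = config.fractions[0]
    rows = []
    for net_rep in range(config.n_networks):
        network, truth = _generate(config, net_rep)
        for draw_rep in range(config.n_constraint_draws):
            for inv_ml, inv_cl in config.variance_grid:
                if inv_ml < 1 or inv_cl < 1:
                    raise ValueError("amplifications must be >= 1")
                plan = VariancePlan(
                    sigma2_adj=1.0, sigma2_ml=1.0 / inv_ml, sigma2_cl=1.0 / inv_cl
                )
                row = _cell(
                    config, network, truth, MethodVariant.MMGG_MCL, fraction,
                    net_rep, draw_rep, plan,
                )
                row["inv_sigma2_ml"] = inv_ml
                row["inv_sigma2_cl"] = inv_cl
                rows.append(row)
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame, by: Sequence[str] = ("variant", "fraction")) -> pd.DataFrame:
    """Mean and standard deviation of NMI per cell."""
    g = table.groupby(list(by))["nmi"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "nmi_mean", "std": "nmi_sd", "count": "n"})


def save_results(table: pd.DataFrame, config: SweepConfig, prefix: str | Path) -> None:
    """Write the long-format CSV plus a JSON metadata sidecar."""
    prefix = Path(prefix)
    table.to_csv(prefix.with_suffix(".csv"), index=False)
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(config.to_metadata(), fh, indent=2)


def plot_sweep(table: pd.DataFrame, path: str | Path) -> None:
    """Render mean-NMI curves per variant (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = summarize(table)
    fig, ax = plt.subplots(figsize=(5, 4))
    for variant, sub in summary.groupby("variant"):
        ax.errorbar(
            sub["fraction"], sub["nmi_mean"], yerr=sub["nmi_sd"].fillna(0),
            marker="o", capsize=2, label=variant,
        )
    ax.set_xlabel("constraint fraction (of all node pairs)")
    ax.set_ylabel("NMI")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
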