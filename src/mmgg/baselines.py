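"""Method variants: the full constraint-weighting method, its single-
constraint forms, and the topology-modification ("ModTop") baseline.

Every variant shares the same weighted-SNMF solver; they differ only in
which constraint types are written into the target matrix O and which
of them get amplified weights:

=============  ============== ============== ========= =========
variant        ML in O        CL in O        ML weight CL weight
=============  ============== ============== ========= =========
snmf           no             no             --        --
modtop_ml      yes            no             1         --
modtop_cl      no             yes            --        1
modtop_mcl     yes            yes            1         1
mmgg_ml        yes            no             amplified --
mmgg_cl        no             yes            --        amplified
mmgg_mlc       yes            yes            amplified 1
mmgg_clm       yes            yes            1         amplified
mmgg_mcl       yes            yes            amplified amplified
=============  ============== ============== ========= =========

``mmgg_mlc`` is the "ML(C)" configuration (cannot-links by topology
modification, must-links weighted) and ``mmgg_clm`` the symmetric
"CL(M)" one.  ModTop is exactly the unit-weight special case, so with
equal variances the trajectories of ``modtop_mcl`` and ``mmgg_mcl``
coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .core import (
    FactorizationResult,
    SolverConfig,
    VariancePlan,
    assign_communities,
    build_weighted_target,
    factorize,
)
from .network import ConstraintSet, Network, Partition

__all__ = ["MethodVariant", "VariantSpec", "VARIANTS", "run_variant", "ConfigurationError"]


class ConfigurationError(ValueError):
    """A variant was invoked without the constraints it encodes."""


class MethodVariant(str, Enum):
    SNMF = "snmf"
    MODTOP_ML = "modtop_ml"
    MODTOP_CL = "modtop_cl"
    MODTOP_MCL = "modtop_mcl"
    MMGG_ML = "mmgg_ml"
    MMGG_CL = "mmgg_cl"
    MMGG_MLC = "mmgg_mlc"
    MMGG_CLM = "mmgg_clm"
    MMGG_MCL = "mmgg_mcl"


@dataclass(frozen=True)
class VariantSpec:
    use_ml: bool
    use_cl: bool
    amplify_ml: bool
    amplify_cl: bool

    @property
    def needs_constraints(self) -> bool:
        return self.use_ml or self.use_cl

    @property
    def sampling_mode(self) -> str:
        """Constraint sampling mode matching the variant's inputs."""
        if self.use_ml and self.use_cl:
            return "both"
        if self.use_ml:
            return "ml_only"
        if self.use_cl:
            return "cl_only"
        return "none"


VARIANTS: dict[MethodVariant, VariantSpec] = {
    MethodVariant.SNMF: VariantSpec(False, False, False, False),
    MethodVariant.MODTOP_ML: VariantSpec(True, False, False, False),
    MethodVariant.MODTOP_CL: VariantSpec(False, True, False, False),
    MethodVariant.MODTOP_MCL: VariantSpec(True, True, False, False),
    MethodVariant.MMGG_ML: VariantSpec(True, False, True, False),
    MethodVariant.MMGG_CL: VariantSpec(False, True, False, True),
    MethodVariant.MMGG_MLC: VariantSpec(True, True, True, False),
    MethodVariant.MMGG_CLM: VariantSpec(True, True, False, True),
    MethodVariant.MMGG_MCL: VariantSpec(True, True, True, True),
}


def run_variant(
    network: Network,
    constraints: ConstraintSet | None,
    k: int,
    variant: MethodVariant | str,
    variances: VariancePlan | None = None,
    config: SolverConfig | None = None,
) -> tuple[Partition, FactorizationResult]:
    """Run one method variant end to end and return (partition, solver result)."""
    variant = MethodVariant(variant)
    spec = VARIANTS[variant]
    if spec.needs_constraints and (constraints is None or constraints.size == 0):
        raise ConfigurationError(
            f"variant {variant.value} encodes constraints but none were supplied"
        )
    constraints = constraints or ConstraintSet.empty()
    used = ConstraintSet(
        constraints.must_link if spec.use_ml else frozenset(),
        constraints.cannot_link if spec.use_cl else frozenset(),
    )
    wt = build_weighted_target(
        network,
        used,
        variances,
        amplify_ml=spec.amplify_ml,
        amplify_cl=spec.amplify_cl,
    )
    result = factorize(wt, k, config)
    return assign_communities(result), result
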