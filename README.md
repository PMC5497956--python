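# mmgg — semi-supervised community detection with pairwise constraints

Community detection — finding groups of nodes more densely connected
internally than externally, e.g. candidate functional modules in
biological interaction networks — often comes with partial prior
knowledge: pairs of nodes known to share a community (*must-links*) or
known not to (*cannot-links*). Constraints are far more trustworthy
than individual edges, and encoding them as if they were mere edges
(adding/removing links and rerunning an unsupervised method) wastes
most of their value — in particular it makes cannot-links look useless.

This package implements a multi-variance Gaussian generative model of
topology and constraints jointly: each pair observation is a Gaussian
draw centred on the membership similarity `x_i·x_j`, with a small
variance for constrained pairs (high confidence) and a larger one for
topology (low confidence). Maximum likelihood reduces to a weighted
symmetric nonnegative matrix factorization

```
min_{X ≥ 0} ‖ W ⊙ (X Xᵀ − O) ‖²_F
```

where `O` is the adjacency matrix with must-link entries set to 1 and
cannot-link entries to 0, and `W` up-weights constrained entries by the
variance ratios (defaults: 5 for must-link, 10 for cannot-link). It is
solved by the monotone multiplicative update
`X ← X · ((W²⊙O)X / (W²⊙XXᵀ)X)^(1/4)` with multi-restart random
initialization. The unit-weight special case ("ModTop": constraints
encoded by topology modification alone) is included as the baseline,
along with GN and LFR benchmark generators with planted ground truth,
ground-truth constraint sampling, NMI scoring, and sweep orchestration
to study what each constraint type contributes.

## Worked example

```python
from mmgg import (GNParams, ConstraintBudget, SolverConfig, generate_gn,
                  sample_constraints, run_variant, nmi)

network, truth = generate_gn(GNParams(z_out=8.0, seed=1))
constraints = sample_constraints(truth, ConstraintBudget(0.03, "both", seed=2))
solver = SolverConfig(n_restarts=20, seed=3)
for variant in ("snmf", "modtop_mcl", "mmgg_mcl"):
    cs = None if variant == "snmf" else constraints
    partition, result = run_variant(network, cs, 4, variant, config=solver)
    print(f"{variant:>10}: NMI {nmi(truth, partition).nmi:.3f}")
```

prints

```
      snmf: NMI 0.642
modtop_mcl: NMI 0.850
  mmgg_mcl: NMI 0.950
```

Here `z_out = 8` means half of each node's expected 16 edges leave its
community — too vague for unsupervised factorization (NMI 0.64 against
the planted 4-way partition). Labeling 3% of all node pairs and
rewriting them into the target matrix (`modtop_mcl`) recovers most of
the structure (0.85); additionally up-weighting those entries by their
confidence (`mmgg_mcl`) recovers still more (0.95). NMI is 1 when the
planted partition is recovered exactly up to relabeling.

The `examples/` scripts cover each capability (generators, detection,
budget sweeps, weight tuning); `mmgg --help` exposes the same
operations as a command line (`generate`, `sample-constraints`,
`detect`, `score`, `sweep`). See `docs/methods.md` for the model,
parameter and protocol details.

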