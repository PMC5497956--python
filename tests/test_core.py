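"""The weighted-target encoding and the multiplicative-update solver.

Oracles: a brute-force dense implementation of the update and loss, the
six-case mean/variance encoding table, and hand-expanded small
instances.
"""

import numpy as np
import pytest

from mmgg import (
    ConstraintSet,
    Network,
    Partition,
    SolverConfig,
    ValidationError,
    VariancePlan,
    WeightedTarget,
    assign_communities,
    build_weighted_target,
    factorize,
    mmgg_loss,
    nmi,
    update_step,
)
from mmgg.core import AssignmentError

from conftest import random_instance


def dense_update(x, W, O, eps=1e-12):
    """Brute-force reference for the multiplicative rule."""
    W2 = W * W
    num = (W2 * O) @ x
    den = (W2 * (x @ x.T)) @ x
    return x * (num / (den + eps)) ** 0.25


def dense_loss(x, W, O):
    return float(((W * (x @ x.T - O)) ** 2).sum())


class TestEncoding:
    def test_six_case_table(self):
        # nodes: 0-1 edge+ML, 2-3 nonedge+ML, 0-2 edge+CL, 1-3 nonedge+CL,
        # 0-3 edge only, 1-2 nonedge only
        a = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (0, 3)]:
            a[i, j] = a[j, i] = 1.0
        net = Network(a)
        cs = ConstraintSet(frozenset({(0, 1), (2, 3)}), frozenset({(0, 2), (1, 3)}))
        wt = build_weighted_target(net, cs, VariancePlan(1.0, 0.2, 0.1))
        O, W = wt.target, wt.weights
        assert (O[0, 1], W[0, 1]) == (1.0, 5.0)  # edge & must-link
        assert (O[2, 3], W[2, 3]) == (1.0, 5.0)  # non-edge & must-link
        assert (O[0, 2], W[0, 2]) == (0.0, 10.0)  # edge & cannot-link
        assert (O[1, 3], W[1, 3]) == (0.0, 10.0)  # non-edge & cannot-link
        assert (O[0, 3], W[0, 3]) == (1.0, 1.0)  # unconstrained edge
        assert (O[1, 2], W[1, 2]) == (0.0, 1.0)  # unconstrained non-edge
        assert np.all(np.diag(W) == 0)

    def test_no_constraints_recovers_plain_snmf_problem(self):
        rng = np.random.default_rng(0)
        a = (rng.random((6, 6)) < 0.5).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        net = Network(a)
        wt = build_weighted_target(net, ConstraintSet.empty())
        assert np.array_equal(wt.target, a)
        expected_w = np.ones((6, 6)) - np.eye(6)
        assert np.array_equal(wt.weights, expected_w)
        assert wt.n_corrections == 0

    def test_unamplified_constraints_have_unit_weight(self):
        a = np.zeros((3, 3))
        net = Network(a)
        cs = ConstraintSet(frozenset({(0, 1)}), frozenset({(1, 2)}))
        wt = build_weighted_target(net, cs, amplify_ml=False, amplify_cl=False)
        assert wt.n_corrections == 0  # pure topology modification
        assert wt.target[0, 1] == 1.0 and wt.target[1, 2] == 0.0

    def test_sparse_correction_storage_scales_with_p(self):
        # only the constrained entries deviate from the base weight
        net, truth = _gn_small()
        from mmgg import ConstraintBudget, sample_constraints

        cs = sample_constraints(truth, ConstraintBudget(0.05, "both", 0))
        wt = build_weighted_target(net, cs)
        assert wt.n_corrections == 2 * cs.size

    def test_amplified_variance_above_adj_rejected(self):
        net = Network(np.zeros((3, 3)))
        cs = ConstraintSet(frozenset({(0, 1)}), frozenset())
        with pytest.raises(ValueError):
            build_weighted_target(net, cs, VariancePlan(1.0, 2.0, 0.1))


def _gn_small():
    from mmgg import GNParams, generate_gn

    return generate_gn(GNParams(z_out=8.0, seed=0))


class TestLoss:
    def test_perfect_reconstruction_is_zero(self, triangle_target):
        assert mmgg_loss(np.ones((3, 1)), triangle_target) == pytest.approx(0.0)

    def test_origin_closed_form(self):
        rng = np.random.default_rng(1)
        wt = random_instance(rng)
        x0 = np.zeros((wt.n_nodes, 3))
        W, O = wt.weights, wt.target
        assert mmgg_loss(x0, wt) == pytest.approx(((W * O) ** 2).sum())

    def test_hand_expanded_triangle(self, triangle_target):
        # X=(1,1,0): residual -1 at the four off-diagonal entries
        # involving node 2, so the full-matrix Frobenius loss is 4
        x = np.array([[1.0], [1.0], [0.0]])
        assert mmgg_loss(x, triangle_target) == pytest.approx(4.0)

    def test_matches_dense_reference(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            wt = random_instance(rng)
            x = rng.uniform(size=(wt.n_nodes, 3))
            assert mmgg_loss(x, wt) == pytest.approx(
                dense_loss(x, wt.weights, wt.target), rel=1e-10
            )

    def test_negative_membership_rejected(self, triangle_target):
        with pytest.raises(ValidationError):
            mmgg_loss(np.array([[1.0], [-0.1], [0.0]]), triangle_target)


class TestUpdate:
    def test_matches_dense_reference_trajectory(self):
        rng = np.random.default_rng(3)
        wt = random_instance(rng, n=10, k=3)
        x = rng.uniform(size=(10, 3))
        xd = x.copy()
        for _ in range(100):
            x = update_step(x, wt)
            xd = dense_update(xd, wt.weights, wt.target)
        np.testing.assert_allclose(x, xd, rtol=1e-10, atol=1e-12)

    def test_unit_weights_reduce_to_plain_snmf(self):
        # with all off-diagonal weights 1 the rule collapses to the
        # standard symmetric-NMF multiplicative update on O
        rng = np.random.default_rng(13)
        a = (rng.random((10, 10)) < 0.4).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        wt = build_weighted_target(Network(a), ConstraintSet.empty())
        mask = 1.0 - np.eye(10)
        x = rng.uniform(size=(10, 3))
        xs = x.copy()
        for _ in range(50):
            x = update_step(x, wt)
            num = (a * mask) @ xs
            den = ((xs @ xs.T) * mask) @ xs
            xs = xs * (num / (den + 1e-12)) ** 0.25
        np.testing.assert_allclose(x, xs, rtol=1e-10, atol=1e-12)

    def test_fixed_point_when_reconstruction_exact(self, triangle_target):
        x = np.ones((3, 1))
        x2 = update_step(x, triangle_target)
        np.testing.assert_allclose(x2, x, rtol=1e-6)

    def test_loss_monotone_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            wt = random_instance(rng, n=int(rng.integers(5, 12)), k=3)
            x = rng.uniform(size=(wt.n_nodes, 3))
            prev = mmgg_loss(x, wt)
            for _ in range(30):
                x = update_step(x, wt)
                cur = mmgg_loss(x, wt)
                assert cur <= prev * (1 + 1e-10) + 1e-12
                prev = cur

    def test_nonnegativity_and_zero_preservation(self):
        rng = np.random.default_rng(5)
        wt = random_instance(rng)
        x = rng.uniform(size=(wt.n_nodes, 3))
        x[2, 1] = 0.0
        x[5, 0] = 0.0
        for _ in range(20):
            x = update_step(x, wt)
            assert np.all(x >= 0)
            assert x[2, 1] == 0.0 and x[5, 0] == 0.0

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(6)
        wt = random_instance(rng)
        x0 = rng.uniform(size=(wt.n_nodes, 3))
        xa, xb = x0.copy(), x0.copy()
        wt_scaled = wt.scaled(7.5)
        for _ in range(50):
            xa = update_step(xa, wt)
            xb = update_step(xb, wt_scaled)
        np.testing.assert_allclose(xa, xb, rtol=1e-8)

    def test_triangle_converges_to_global_optimum(self, triangle_target):
        # brute-force grid search confirms (1,1,1) (up to scale) minimizes
        # the 3-variable objective; the update must reach loss ~ 0
        x = np.array([[1.0], [1.0], [0.5]])
        for _ in range(500):
            x = update_step(x, triangle_target)
        assert mmgg_loss(x, triangle_target) < 1e-8
        assert np.allclose(x / x[0], 1.0, atol=1e-4)


class TestFactorize:
    def test_seeded_determinism(self, two_clique_network):
        net, _ = two_clique_network
        wt = build_weighted_target(net, ConstraintSet.empty())
        cfg = SolverConfig(n_restarts=3, seed=42)
        r1 = factorize(wt, 2, cfg)
        r2 = factorize(wt, 2, cfg)
        assert r1.loss == r2.loss
        np.testing.assert_array_equal(r1.membership, r2.membership)

    def test_two_block_network_recovered(self, two_clique_network):
        net, truth = two_clique_network
        wt = build_weighted_target(net, ConstraintSet.empty())
        res = factorize(wt, 2, SolverConfig(n_restarts=5, seed=1))
        part = assign_communities(res)
        assert nmi(truth, part).nmi == pytest.approx(1.0)

    def test_best_restart_has_minimum_loss(self, two_clique_network):
        net, _ = two_clique_network
        wt = build_weighted_target(net, ConstraintSet.empty())
        cfg = SolverConfig(n_restarts=6, seed=3)
        res = factorize(wt, 2, cfg)
        # re-run each restart manually from the same stream of inits
        rng = np.random.default_rng(3)
        losses = []
        from mmgg.core import _run_restart

        for _ in range(6):
            x0 = rng.uniform(size=(net.n_nodes, 2))
            losses.append(_run_restart(x0, wt, cfg)[1])
        assert res.loss == pytest.approx(min(losses))
        assert res.loss == pytest.approx(mmgg_loss(res.membership, wt), rel=1e-12)

    def test_k_out_of_range_rejected(self, triangle_target):
        with pytest.raises(ValueError):
            factorize(triangle_target, 4, SolverConfig(n_restarts=1, seed=0))


class TestAssign:
    def test_argmax_and_tie_rule(self):
        from mmgg import FactorizationResult

        x = np.array([[0.9, 0.1], [0.5, 0.5], [0.1, 0.7]])
        part = assign_communities(
            FactorizationResult(membership=x, loss=0.0)
        )
        assert part.labels.tolist() == [1, 1, 2]  # tie -> smaller index

    def test_permutation_rows_give_singletons(self):
        from mmgg import FactorizationResult

        x = np.eye(3)[[2, 0, 1]]
        part = assign_communities(FactorizationResult(membership=x, loss=0.0))
        assert sorted(part.labels.tolist()) == [1, 2, 3]

    def test_zero_row_raises(self):
        from mmgg import FactorizationResult

        x = np.array([[0.4, 0.6], [0.0, 0.0]])
        with pytest.raises(AssignmentError, match="1"):
            assign_communities(FactorizationResult(membership=x, loss=0.0))
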