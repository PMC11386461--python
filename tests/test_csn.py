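"""CSN displacement model, loss and CMA-ES optimization."""

import numpy as np
import pytest

from csnnorm import (
    DEGConfig,
    DisplacementParams,
    GroupDesign,
    LossConfig,
    OptimizerConfig,
    StandardizationWeights,
    build_list_scheme,
    cluster_genes,
    displace,
    evaluate_pair,
    loss,
    optimize,
    standardize,
)
from csnnorm._cmaes import cma_es_minimize, default_population_size
from csnnorm._fcm import fuzzy_c_means
from csnnorm.csn import GeneClustering, _loss_from_report, apply_displacement
from csnnorm.evaluation import DEGListScheme

from conftest import make_matrix


def identity_clustering(n_genes, k=1):
    membership = np.zeros((n_genes, k))
    membership[:, 0] = 1.0
    return GeneClustering(k=k, membership=membership,
                          assignment=np.zeros(n_genes, dtype=int))


class TestParams:
    def test_flat_length_is_4k_plus_4(self):
        assert DisplacementParams.identity(50).encode().size == 204

    def test_encode_decode_roundtrip_is_exact(self):
        rng = np.random.default_rng(0)
        for k in (1, 3, 50):
            flat = rng.uniform(-2, 2, 4 * k + 4)
            flat[4 * k:] = np.abs(flat[4 * k:])  # admissible weights
            back = DisplacementParams.decode(flat, k).encode()
            np.testing.assert_array_equal(back, flat)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            DisplacementParams.decode(np.zeros(10), 3)

    def test_offset_weights_are_made_admissible(self):
        k = 2
        offsets = np.zeros(4 * k + 4)
        offsets[4 * k:] = [-2.0, -2.0, 0.5, 0.2]  # w_xx, w_yx driven negative
        p = DisplacementParams.from_offsets(offsets, k)
        p.weights.validate()
        assert p.weights.w_xx + p.weights.w_yx >= 1e-3


class TestStandardize:
    def test_identity_weights_pass_through_bit_for_bit(self):
        rng = np.random.default_rng(1)
        X = make_matrix(rng.uniform(0, 12, (10, 4)))
        Y = make_matrix(rng.uniform(0, 12, (10, 5)))
        Xs, Ys, moments = standardize(X, Y, StandardizationWeights())
        np.testing.assert_array_equal(Xs.values.to_numpy(),
                                      X.values.to_numpy())
        np.testing.assert_array_equal(Ys.values.to_numpy(),
                                      Y.values.to_numpy())
        np.testing.assert_array_equal(moments.mu_x_st, moments.mu_x)

    def test_full_borrowing_moves_x_onto_y_moments(self):
        # single gene, X=(2,4), Y=(6,8); w_xx=0, w_yx=1 maps X onto Y exactly
        X = make_matrix([[2.0, 4.0]])
        Y = make_matrix([[6.0, 8.0]])
        w = StandardizationWeights(w_xx=0.0, w_yx=1.0, w_yy=1.0, w_xy=0.0)
        Xs, _, moments = standardize(X, Y, w)
        np.testing.assert_allclose(Xs.values.to_numpy(), [[6.0, 8.0]])
        assert moments.sigma_x == pytest.approx(np.sqrt(2))  # ddof=1

    def test_constant_gene_moves_to_blended_mean(self):
        X = make_matrix([[3.0, 3.0, 3.0]])
        Y = make_matrix([[5.0, 7.0, 9.0]])
        w = StandardizationWeights(w_xx=1.0, w_yx=1.0)
        Xs, _, moments = standardize(X, Y, w)
        np.testing.assert_allclose(Xs.values.to_numpy(),
                                   moments.mu_x_st[0])
        assert moments.mu_x_st[0] == pytest.approx(5.0)  # (3 + 7) / 2

    def test_denominator_guard(self):
        X, Y = make_matrix([[1.0, 2.0]]), make_matrix([[1.0, 2.0]])
        with pytest.raises(ValueError, match="1e-3|0.001"):
            standardize(X, Y, StandardizationWeights(w_xx=0.0, w_yx=0.0))


class TestDisplace:
    def test_neutral_parameters_are_identity(self):
        rng = np.random.default_rng(2)
        X = make_matrix(rng.uniform(0, 12, (6, 3)))
        Y = make_matrix(rng.uniform(0, 12, (6, 3)))
        cl = identity_clustering(6)
        Xn, Yn = displace(X, Y, cl, DisplacementParams.identity(1))
        np.testing.assert_array_equal(Xn.values.to_numpy(), X.values.to_numpy())
        np.testing.assert_array_equal(Yn.values.to_numpy(), Y.values.to_numpy())

    def test_affine_arithmetic(self):
        X = make_matrix([[3.0]])
        Y = make_matrix([[3.0]])
        cl = identity_clustering(1)
        p = DisplacementParams(np.array([2.0]), np.array([1.0]),
                               np.array([1.0]), np.array([0.0]),
                               StandardizationWeights())
        Xn, Yn = displace(X, Y, cl, p)
        assert Xn.values.iloc[0, 0] == 7.0
        assert Yn.values.iloc[0, 0] == 3.0

    def test_each_gene_uses_its_own_cluster(self):
        X = make_matrix(np.array([[1.0, 1.0], [1.0, 1.0]]))
        Y = make_matrix(np.array([[1.0, 1.0], [1.0, 1.0]]))
        membership = np.array([[1.0, 0.0], [0.0, 1.0]])
        cl = GeneClustering(k=2, membership=membership,
                            assignment=np.array([0, 1]))
        p = DisplacementParams(np.array([2.0, 3.0]), np.array([0.0, 10.0]),
                               np.ones(2), np.zeros(2),
                               StandardizationWeights())
        Xn, _ = displace(X, Y, cl, p)
        np.testing.assert_allclose(Xn.values.to_numpy(),
                                   [[2.0, 2.0], [13.0, 13.0]])


class TestClustering:
    def test_single_cluster(self):
        X = make_matrix(np.random.default_rng(0).uniform(0, 10, (8, 3)))
        cl = cluster_genes(X, X, k=1, seed=0)
        np.testing.assert_array_equal(cl.membership, 1.0)
        assert (cl.assignment == 0).all()

    def test_two_blobs_recovered_up_to_label_permutation(self):
        rng = np.random.default_rng(4)
        lo = rng.normal(2.0, 0.1, (30, 6))
        hi = rng.normal(10.0, 0.1, (30, 6))
        X = make_matrix(np.vstack([lo, hi]))
        cl = cluster_genes(X, X, k=2, seed=1)
        first, second = cl.assignment[:30], cl.assignment[30:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_deterministic_given_seed(self, small_pair):
        Xp, Yp, _ = small_pair
        a = cluster_genes(Xp, Yp, k=5, seed=3).assignment
        b = cluster_genes(Xp, Yp, k=5, seed=3).assignment
        np.testing.assert_array_equal(a, b)

    def test_k_larger_than_gene_count_errors(self):
        X = make_matrix(np.ones((3, 2)))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_genes(X, X, k=5)

    def test_membership_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        u, _ = fuzzy_c_means(rng.uniform(0, 10, (40, 5)), k=4, seed=2)
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)


class FakeReport:
    def __init__(self, csc, iou_x, iou_y):
        self.csc, self.iou_x, self.iou_y = csc, iou_x, iou_y


class TestLoss:
    def test_penalty_vanishes_at_t0(self):
        cfg = LossConfig(t=0.0, m=100.0)
        assert _loss_from_report(FakeReport(1.0, 0.2, 0.3), cfg) == \
            pytest.approx(-1.0 - 0.2 - 0.3)

    def test_penalty_arithmetic(self):
        cfg = LossConfig(t=0.75, m=100.0)
        value = _loss_from_report(FakeReport(1.0, 0.70, 0.70), cfg)
        assert value == pytest.approx(-1.9)

    def test_penalty_zero_iff_both_ious_reach_t(self):
        cfg = LossConfig(t=0.7, m=100.0)
        at = _loss_from_report(FakeReport(0.0, 0.7, 0.7), cfg)
        assert at == pytest.approx(-1.4)
        below = _loss_from_report(FakeReport(0.0, 0.7, 0.699), cfg)
        assert below > -1.399  # strictly positive penalty

    def test_identity_loss_is_minus_csc_minus_two(self, design, small_pair,
                                                  floor_config):
        Xp, Yp, _ = small_pair
        cl = cluster_genes(Xp, Yp, k=4, seed=0)
        scheme = build_list_scheme(Xp, Yp, design, floor_config)
        baseline = scheme.condition_lists
        cfg = LossConfig(t=0.7, m=100.0, deg_config=floor_config)
        value = loss(Xp, Yp, DisplacementParams.identity(4), cl,
                     baseline, design, cfg)
        expected = -evaluate_pair(scheme).csc - 2.0
        assert value == pytest.approx(expected, abs=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="t must"):
            LossConfig(t=1.5)
        with pytest.raises(ValueError, match="m must"):
            LossConfig(m=0.0)


class TestCMAES:
    def test_minimizes_a_shifted_quadratic(self):
        target = np.array([0.3, -0.5, 0.1])
        res = cma_es_minimize(lambda x: ((x - target) ** 2).sum(),
                              np.zeros(3), sigma0=0.3, bounds=(-2, 2),
                              max_generations=80, seed=0)
        np.testing.assert_allclose(res.best_x, target, atol=1e-3)

    def test_default_population_size(self):
        assert default_population_size(204) == 19

    def test_best_never_worse_than_start_and_history_monotone(self):
        fun = lambda x: float((x**2).sum())
        res = cma_es_minimize(fun, np.full(4, 0.5), sigma0=0.1,
                              bounds=(-1, 1), max_generations=10, seed=1)
        assert res.best_f <= fun(np.full(4, 0.5))
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))

    def test_candidates_respect_bounds(self):
        seen = []
        fun = lambda x: (seen.append(x.copy()), float((x**2).sum()))[1]
        cma_es_minimize(fun, np.zeros(2), sigma0=1.0, bounds=(-0.5, 0.5),
                        max_generations=5, popsize=8, seed=2)
        arr = np.array(seen)
        assert (arr >= -0.5).all() and (arr <= 0.5).all()

    def test_non_finite_start_raises(self):
        with pytest.raises(ValueError, match="finite"):
            cma_es_minimize(lambda x: np.nan, np.zeros(2), 0.1, (-1, 1), 5)


@pytest.fixture(scope="module")
def tiny_run(request):
    from csnnorm import SimConfig, pair_by_orthologs, simulate_pair
    cfg = SimConfig(n_genes=250, seed=5)
    X, Y, truth = simulate_pair(cfg)
    Xp, Yp = pair_by_orthologs(X, Y, truth.ortholog_map)
    design = GroupDesign("C1", "C2")
    cl = cluster_genes(Xp, Yp, k=8, seed=5)
    result = optimize(Xp, Yp, design, cl,
                      LossConfig(t=0.7, m=100.0),
                      OptimizerConfig(max_generations=6, seed=5))
    return Xp, Yp, design, cl, result


class TestOptimize:
    def test_best_loss_never_exceeds_identity_loss(self, tiny_run):
        *_, result = tiny_run
        assert result.best_loss <= result.initial_loss

    def test_objective_history_is_non_increasing(self, tiny_run):
        *_, result = tiny_run
        h = result.objective_history
        assert len(h) == 7  # identity + one entry per generation
        assert all(a >= b - 1e-12 for a, b in zip(h, h[1:]))

    def test_final_csc_at_least_initial(self, tiny_run):
        *_, result = tiny_run
        assert result.report.csc >= result.initial_report.csc - 1e-12

    def test_same_seed_reproduces_history(self, tiny_run):
        Xp, Yp, design, cl, result = tiny_run
        again = optimize(Xp, Yp, design, cl,
                         LossConfig(t=0.7, m=100.0),
                         OptimizerConfig(max_generations=6, seed=5))
        assert again.objective_history == result.objective_history
        np.testing.assert_array_equal(again.best_params.encode(),
                                      result.best_params.encode())

    def test_best_params_reproduce_the_returned_matrices(self, tiny_run):
        Xp, Yp, design, cl, result = tiny_run
        xn, yn = apply_displacement(Xp, Yp, cl, result.best_params)
        np.testing.assert_array_equal(xn.values.to_numpy(),
                                      result.x_new.values.to_numpy())
        np.testing.assert_array_equal(yn.values.to_numpy(),
                                      result.y_new.values.to_numpy())
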