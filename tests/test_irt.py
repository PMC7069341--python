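import itertools

import numpy as np
import pytest

from equatesim.irt import (
    InsufficientAnchorError,
    TwoParameterLogistic,
    gaussian_quadrature,
    irf_2pl,
    link_scales,
    lord_wingersky,
    marginal_score_distribution,
)


def simulate_2pl(slopes, locations, thetas, seed):
    rng = np.random.default_rng(seed)
    p = irf_2pl(thetas[:, None], slopes[None, :], locations[None, :])
    return (p > rng.random(p.shape)).astype(int)


class TestItemResponseFunction:
    def test_half_at_difficulty(self):
        assert irf_2pl(1.3, 0.7, 1.3) == pytest.approx(0.5)

    def test_asymptotes(self):
        assert irf_2pl(60.0, 1.0, 0.0) == pytest.approx(1.0)
        assert irf_2pl(-60.0, 1.0, 0.0) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        assert irf_2pl(1.0, 1.0, 0.0, D=1.0) == pytest.approx(1 / (1 + np.exp(-1)))


class TestLordWingersky:
    def test_single_bernoulli(self):
        d = lord_wingersky([0.5])
        assert np.allclose(d.probabilities, [0.5, 0.5])

    def test_point_mass_when_all_certain(self):
        d = lord_wingersky([1.0, 1.0, 1.0])
        assert np.allclose(d.probabilities, [0, 0, 0, 1])

    @pytest.mark.parametrize("n_items", [3, 7, 12])
    def test_equals_pattern_enumeration(self, n_items, rng):
        """Oracle: full 2^J enumeration of response patterns."""
        p = rng.random(n_items)
        brute = np.zeros(n_items + 1)
        for pat in itertools.product([0, 1], repeat=n_items):
            pr = np.prod([pi if r else 1 - pi for pi, r in zip(p, pat)])
            brute[sum(pat)] += pr
        assert np.abs(lord_wingersky(p).probabilities - brute).max() < 1e-12


class TestMarginalScoreDistribution:
    def test_single_quadrature_point_equals_conditional(self):
        a, b = np.array([1.0, 2.0]), np.array([-0.5, 0.5])
        m = marginal_score_distribution(a, b, np.array([0.3]), np.array([1.0]))
        cond = lord_wingersky(irf_2pl(0.3, a, b))
        assert np.allclose(m.probabilities, cond.probabilities)

    def test_symmetric_bank_symmetric_density(self):
        a = np.ones(6)
        b = np.zeros(6)
        nodes, w = gaussian_quadrature(41)
        m = marginal_score_distribution(a, b, nodes, w)
        assert np.allclose(m.probabilities, m.probabilities[::-1], atol=1e-12)
        assert m.mean == pytest.approx(3.0)

    def test_two_point_density_hand_mixture(self):
        a, b = np.array([1.0, 1.0]), np.array([0.0, 0.0])
        grid = np.array([-1.0, 1.0])
        w = np.array([0.4, 0.6])
        m = marginal_score_distribution(a, b, grid, w)
        expected = 0.4 * lord_wingersky(irf_2pl(-1.0, a, b)).probabilities \
            + 0.6 * lord_wingersky(irf_2pl(1.0, a, b)).probabilities
        assert np.allclose(m.probabilities, expected)

    def test_rejects_unnormalized_weights(self):
        with pytest.raises(ValueError):
            marginal_score_distribution(
                np.ones(2), np.zeros(2), np.array([0.0, 1.0]), np.array([0.5, 0.2])
            )


class TestTwoParameterLogisticFit:
    def test_parameter_recovery_rmse_decreases_with_n(self, rng):
        """RMSE (averaged over replications) shrinks as the calibration
        sample grows."""
        slopes = rng.lognormal(-0.1, 0.3, 30)
        locations = rng.normal(0, 1, 30)
        rmse = []
        for i, n in enumerate((500, 1000, 2500)):
            per_rep = []
            for r in range(3):
                th = np.random.default_rng(100 + 10 * i + r).standard_normal(n)
                Y = simulate_2pl(slopes, locations, th, seed=200 + 10 * i + r)
                m = TwoParameterLogistic().fit(Y)
                per_rep.append(np.sqrt(np.mean(
                    (m.location_ - locations) ** 2 + (m.slope_ - slopes) ** 2)))
            rmse.append(np.mean(per_rep))
        assert rmse[0] > rmse[1] > rmse[2]
        assert rmse[2] < 0.2

    def test_loglikelihood_nondecreasing(self, rng):
        Y = simulate_2pl(rng.lognormal(0, 0.3, 15), rng.normal(0, 1, 15),
                         rng.standard_normal(400), seed=5)
        m = TwoParameterLogistic().fit(Y)
        assert np.all(np.diff(m.loglik_path_) > -1e-7)

    def test_interchanged_columns_get_identical_estimates(self, rng):
        Y = simulate_2pl(np.full(10, 1.2), np.linspace(-1, 1, 10),
                         rng.standard_normal(600), seed=9)
        Y2 = np.column_stack([Y, Y[:, 3]])  # duplicate one column
        m = TwoParameterLogistic().fit(Y2)
        assert m.slope_[3] == pytest.approx(m.slope_[-1], abs=1e-6)
        assert m.location_[3] == pytest.approx(m.location_[-1], abs=1e-6)

    def test_degenerate_column_clamped_not_dropped(self, rng):
        Y = simulate_2pl(np.ones(8), np.zeros(8), rng.standard_normal(300), seed=3)
        Y[:, 0] = 1  # everyone correct
        m = TwoParameterLogistic().fit(Y)
        assert m.degenerate_items_[0]
        assert m.location_[0] == -m.location_bound
        assert m.slope_[0] == m.slope_floor
        assert m.slope_.size == 8

    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            TwoParameterLogistic().fit(np.array([[0, 2], [1, 0]]))

    def test_scale_indeterminacy_of_implied_distribution(self):
        """Affinely transforming the generating ability scale (with the
        compensating item-parameter transform) leaves the model-implied
        score distribution unchanged."""
        a = np.array([0.8, 1.1, 1.4])
        b = np.array([-0.6, 0.1, 0.9])
        nodes, w = gaussian_quadrature(41)
        d1 = marginal_score_distribution(a, b, nodes, w)
        A, B = 2.0, 1.0
        d2 = marginal_score_distribution(a / A, A * b + B, A * nodes + B, w)
        assert np.allclose(d1.probabilities, d2.probabilities, atol=1e-12)


class TestScaleLinking:
    def test_identity_when_anchors_identical(self):
        a = np.array([0.8, 1.0, 1.3])
        b = np.array([-0.5, 0.2, 0.9])
        t = link_scales(a, b, a, b)
        assert t.A == pytest.approx(1.0, abs=1e-4)
        assert t.B == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize("method", ["stocking-lord", "haebara", "mean-mean", "mean-sigma"])
    def test_recovers_known_transform(self, method):
        a = np.array([0.7, 1.0, 1.2, 1.6])
        b = np.array([-1.0, -0.2, 0.4, 1.1])
        A0, B0 = 1.3, -0.4
        # source calibration sees the same items on its own scale
        a_src, b_src = a * A0, (b - B0) / A0
        t = link_scales(a, b, a_src, b_src, method=method)
        assert t.A == pytest.approx(A0, abs=2e-3)
        assert t.B == pytest.approx(B0, abs=2e-3)
        a_back, b_back = t.transform_items(a_src, b_src)
        assert np.allclose(a_back, a, atol=5e-3)
        assert np.allclose(b_back, b, atol=5e-3)

    def test_single_anchor_item_raises(self):
        with pytest.raises(InsufficientAnchorError):
            link_scales([1.0], [0.0], [1.0], [0.0])
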