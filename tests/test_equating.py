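import numpy as np
import pytest
from sklearn.base import clone

from equatesim.distributions import BivariateScoreTable, ScoreDistribution
from equatesim.equating import (
    EquatingFunction,
    EquipercentileEquating,
    IRTKernelEquating,
    IRTObservedScoreEquating,
    KernelEquating,
    chained_equate,
    design_function,
    equipercentile_equate,
    kernel_equate,
)
from equatesim.irt import irf_2pl


@pytest.fixture()
def bell():
    x = np.arange(31)
    return ScoreDistribution(np.exp(-0.5 * ((x - 14) / 5.0) ** 2))


@pytest.fixture()
def shifted_pair():
    """dist_Y is dist_X shifted by exactly +3 score points."""
    p = np.exp(-0.5 * ((np.arange(31) - 12) / 4.0) ** 2)
    p /= p.sum()
    dx = ScoreDistribution(np.concatenate([p, np.zeros(3)]))
    dy = ScoreDistribution(np.concatenate([np.zeros(3), p]))
    return dx, dy


def simulate_group(slopes, locations, n, seed, shift=0.0):
    rng = np.random.default_rng(seed)
    th = rng.standard_normal(n)
    p = irf_2pl(th[:, None], slopes[None, :], (locations + shift)[None, :])
    return (p > rng.random(p.shape)).astype(int)


class TestEquatingFunction:
    def test_rejects_decreasing(self):
        with pytest.raises(ValueError):
            EquatingFunction(np.arange(3.0), np.array([0.0, 2.0, 1.0]))

    def test_interpolates(self):
        f = EquatingFunction(np.arange(3.0), np.array([0.0, 2.0, 4.0]))
        assert f(0.5) == pytest.approx(1.0)


class TestEquipercentile:
    def test_identity_on_equal_distributions(self, bell):
        f = equipercentile_equate(bell, bell)
        assert np.abs(f.y - f.x).max() < 1e-10

    def test_hand_computed_small_example(self):
        # X uniform on {0,1}; Y uniform on {0,1,2}: percentile-rank arithmetic
        # gives e(0) = 0.25 and e(1) = 1.75
        dx = ScoreDistribution([0.5, 0.5])
        dy = ScoreDistribution([1 / 3, 1 / 3, 1 / 3])
        f = equipercentile_equate(dx, dy)
        assert np.allclose(f.y, [0.25, 1.75])

    def test_exact_shift_recovered(self, shifted_pair):
        f = equipercentile_equate(*shifted_pair)
        interior = slice(4, 22)
        assert np.abs(f.y[interior] - (f.x[interior] + 3)).max() < 1e-10

    def test_zero_frequency_scores_keep_monotonicity(self):
        p = np.array([0.1, 0.0, 0.0, 0.4, 0.0, 0.5])
        q = np.array([0.2, 0.3, 0.0, 0.0, 0.1, 0.4])
        f = equipercentile_equate(ScoreDistribution(p), ScoreDistribution(q))
        assert np.all(np.diff(f.y) >= 0)
        assert f.y.min() >= -0.5 and f.y.max() <= 5.5


class TestKernelEquating:
    def test_identity_on_equal_distributions(self, bell):
        f = kernel_equate(bell, bell)
        assert np.abs(f.y - f.x).max() < 1e-6

    def test_exact_shift_recovered(self, shifted_pair):
        f = kernel_equate(*shifted_pair)
        interior = slice(4, 22)
        assert np.abs(f.y[interior] - (f.x[interior] + 3)).max() < 1e-6

    def test_round_trip_symmetry(self, bell, shifted_pair):
        dx, dy = shifted_pair
        fwd = kernel_equate(dx, dy)
        back = kernel_equate(dy, dx)
        interior = slice(4, 22)
        assert np.abs(back(fwd.y[interior]) - fwd.x[interior]).max() < 1e-6

    def test_large_bandwidth_approaches_linear_equating(self, bell, shifted_pair):
        dx, dy = shifted_pair
        f = kernel_equate(dx, dy, h_x=1e3, h_y=1e3)
        linear = dy.mean + dy.sd / dx.sd * (f.x - dx.mean)
        assert np.abs(f.y - linear).max() < 0.05


class TestChained:
    def test_identity_composition(self):
        ident = EquatingFunction(np.arange(11.0), np.arange(11.0))
        f = chained_equate(ident, ident)
        assert np.allclose(f.y, f.x)

    def test_affine_composition(self):
        l1 = EquatingFunction(np.arange(11.0), np.arange(11.0) / 2)
        l2 = EquatingFunction(np.arange(11.0), np.arange(11.0) + 1)
        f = chained_equate(l1, l2)
        assert np.allclose(f.y, np.arange(11.0) / 2 + 1)

    def test_matches_pointwise_oracle(self, bell, shifted_pair):
        dx, dy = shifted_pair
        l1 = equipercentile_equate(dx, bell)
        l2 = equipercentile_equate(bell, dy)
        f = chained_equate(l1, l2)
        oracle = [np.interp(l1.y[i], l2.x, l2.y) for i in range(l1.x.size)]
        assert np.allclose(f.y, oracle)


class TestDesignFunction:
    def test_eg_identity(self, bell):
        out = design_function("eg", bell, bell)
        assert out[0] is bell and out[1] is bell

    def test_neat_margins(self):
        tp = BivariateScoreTable(np.array([[1.0, 1.0], [0.0, 2.0]]))
        tq = BivariateScoreTable(np.ones((2, 2)))
        xp, ap, aq, yq = design_function("neat", tp, tq)
        assert np.allclose(xp.probabilities, [0.5, 0.5])
        assert np.allclose(ap.probabilities, [0.25, 0.75])
        assert np.allclose(aq.probabilities, [0.5, 0.5])

    def test_mismatched_inputs_raise(self, bell):
        with pytest.raises(ValueError):
            design_function("neat", bell, bell)
        with pytest.raises(ValueError):
            design_function("circle", bell, bell)


class TestIRTEstimators:
    slopes = np.linspace(0.7, 1.5, 30)
    locations = np.linspace(-1.5, 1.5, 30)

    def test_null_equating_near_identity(self):
        X = simulate_group(self.slopes, self.locations, 1500, seed=1)
        Y = simulate_group(self.slopes, self.locations, 1500, seed=2)
        f = IRTObservedScoreEquating().fit(X, Y).equating_function_
        assert np.abs(f.y[4:27] - f.x[4:27]).max() < 0.5

    def test_irtose_and_irtke_agree_on_smooth_null(self):
        X = simulate_group(self.slopes, self.locations, 2000, seed=3)
        Y = simulate_group(self.slopes, self.locations, 2000, seed=4)
        a = IRTObservedScoreEquating().fit(X, Y).equating_function_
        b = IRTKernelEquating().fit(X, Y).equating_function_
        assert np.abs(a.y[4:27] - b.y[4:27]).max() < 0.15

    def test_known_difficulty_shift_moves_equated_scores(self):
        """Form Y uniformly harder by delta: equating X to Y must map
        interior scores downward by a consistent amount."""
        X = simulate_group(self.slopes, self.locations, 2000, seed=5)
        Y = simulate_group(self.slopes, self.locations, 2000, seed=6, shift=0.4)
        f = IRTObservedScoreEquating().fit(X, Y).equating_function_
        diff = f.y[8:24] - f.x[8:24]
        assert np.all(diff < 0)
        assert diff.std() < 0.5

    def test_neat_requires_anchor(self):
        X = simulate_group(self.slopes, self.locations, 300, seed=7)
        Y = simulate_group(self.slopes, self.locations, 300, seed=8)
        with pytest.raises(ValueError):
            IRTObservedScoreEquating(design="neat", anchor_x=[0]).fit(X, Y)

    def test_transform_interpolates_fitted_function(self):
        X = simulate_group(self.slopes, self.locations, 800, seed=9)
        est = IRTKernelEquating().fit(X, X.copy())
        vals = est.transform([10.0, 10.5, 20.0])
        assert vals.shape == (3,)
        assert np.all(np.diff(vals) > 0)


class TestSklearnProtocol:
    @pytest.mark.parametrize("est", [
        EquipercentileEquating(n_items_x=30, n_items_y=30),
        KernelEquating(n_items_x=30, n_items_y=30, presmooth_degree=4),
        IRTObservedScoreEquating(mixture_weight=0.3),
        IRTKernelEquating(),
    ])
    def test_get_set_params_and_clone(self, est):
        params = est.get_params()
        est2 = clone(est)
        assert est2.get_params() == params
        est2.set_params(**params)
        assert est2.get_params() == params
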