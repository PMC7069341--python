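import numpy as np
import pytest

from equatesim.simulation import (
    ConditionSpec,
    InfeasibleConditionError,
    anchor_count,
    assemble_pseudo_tests,
    condition_grid,
    run_condition,
    run_replication,
    sample_groups,
    simulate_irt_responses,
)


class TestGrid:
    def test_full_grid_has_240_cells(self):
        assert len(condition_grid("eg")) == 240
        assert len(condition_grid("neat")) == 240

    @pytest.mark.parametrize("length,expected", [(30, 9), (45, 14)])
    def test_anchor_is_30_percent_rounded_half_up(self, length, expected):
        assert anchor_count(length) == expected

    def test_condition_validation(self):
        with pytest.raises(ValueError):
            ConditionSpec("XX", 500, 30, "PTPG", "IE")
        with pytest.raises(ValueError):
            ConditionSpec("EE", 500, 30, "PTPG", "IE", replications=1)

    def test_lssg_feasibility_rule(self):
        assert not ConditionSpec("EE", 500, 45, "PTPG", "LSSG-EE", "eg").feasible
        assert ConditionSpec("EE", 500, 45, "PTPG", "LSSG-EE", "neat").feasible
        assert ConditionSpec("EE", 500, 30, "PTPG", "LSSG-EE", "eg").feasible


class TestAssembly:
    def test_eg_disjoint_sets(self, rng):
        a = assemble_pseudo_tests(30, "eg", rng)
        assert a.x_items.size == 30 and a.y_items.size == 30
        assert np.intersect1d(a.x_items, a.y_items).size == 0

    def test_eg_45_disjoint_infeasible(self, rng):
        with pytest.raises(InfeasibleConditionError):
            assemble_pseudo_tests(45, "eg", rng)

    def test_eg_45_overlapping_draw(self, rng):
        a = assemble_pseudo_tests(45, "eg", rng, allow_overlap=True)
        assert np.unique(a.x_items).size == 45
        assert np.unique(a.y_items).size == 45

    def test_neat_internal_anchor_geometry(self, rng):
        a = assemble_pseudo_tests(30, "neat", rng)
        assert a.n_anchor == 9
        assert np.array_equal(a.x_items[:9], a.anchor_items)
        assert np.array_equal(a.y_items[:9], a.anchor_items)
        distinct = np.unique(np.concatenate([a.x_items, a.y_items]))
        assert distinct.size == 51  # 9 common + 2 * 21 unique

    def test_deterministic_under_seed(self):
        a1 = assemble_pseudo_tests(30, "neat", np.random.default_rng(5))
        a2 = assemble_pseudo_tests(30, "neat", np.random.default_rng(5))
        assert np.array_equal(a1.x_items, a2.x_items)


class TestGroupSampling:
    def test_eg_disjoint_groups(self, small_population, rng):
        p, q = sample_groups(small_population, 400, "eg", rng)
        assert p.size == q.size == 400
        assert np.intersect1d(p, q).size == 0

    def test_neat_mean_separation(self, small_population, rng):
        p, q = sample_groups(small_population, 300, "neat", rng)
        s = small_population.sum_scores("II")
        assert s[p].mean() > s[q].mean()

    def test_insufficient_population_raises(self, small_population, rng):
        with pytest.raises(ValueError):
            sample_groups(small_population, 700, "eg", rng)


class TestIRTResponses:
    def test_deterministic(self):
        out1 = simulate_irt_responses(np.ones(5), np.zeros(5),
                                      np.linspace(-1, 1, 7),
                                      np.random.default_rng(3))
        out2 = simulate_irt_responses(np.ones(5), np.zeros(5),
                                      np.linspace(-1, 1, 7),
                                      np.random.default_rng(3))
        assert np.array_equal(out1, out2)

    def test_high_ability_on_easy_items_all_correct(self, rng):
        out = simulate_irt_responses(np.full(10, 2.0), np.full(10, -3.0),
                                     np.full(20, 6.0), rng)
        assert out.mean() > 0.99

    def test_item_means_match_probabilities(self, rng):
        """Binomial check at n = 2500 within 3 standard errors."""
        from equatesim.irt import irf_2pl
        slopes = np.linspace(0.6, 1.6, 12)
        locs = np.linspace(-1, 1, 12)
        thetas = rng.standard_normal(2500)
        out = simulate_irt_responses(slopes, locs, thetas, rng)
        p = irf_2pl(thetas[:, None], slopes[None, :], locs[None, :]).mean(axis=0)
        se = np.sqrt(p * (1 - p) / 2500)
        assert np.all(np.abs(out.mean(axis=0) - p) < 3.5 * se)


class TestReplicationLoop:
    def test_null_override_near_identity(self, small_population):
        cond = ConditionSpec("EE", 300, 30, "PTPG", "IE", "eg")
        res = run_replication(cond, small_population,
                              np.random.default_rng(1),
                              methods=("EE", "KE"),
                              force_identical_tests=True)
        for arr in res.methods.values():
            # single replication: only a coarse near-identity check
            assert np.abs(arr[8:24] - np.arange(30 + 1.0)[8:24]).max() < 1.5

    def test_lssg_infeasible_at_45_in_eg(self, small_population):
        cond = ConditionSpec("EE", 300, 45, "PTPG", "LSSG-EE", "eg")
        with pytest.raises(InfeasibleConditionError):
            run_replication(cond, small_population, np.random.default_rng(1))

    def test_replay_is_deterministic(self, small_population):
        cond = ConditionSpec("KE", 200, 30, "PTPG", "IE", "eg")
        r1 = run_replication(cond, small_population, np.random.default_rng(9))
        r2 = run_replication(cond, small_population, np.random.default_rng(9))
        assert np.array_equal(r1.methods["KE"], r2.methods["KE"])
        assert np.array_equal(r1.x_counts, r2.x_counts)

    def test_run_condition_smoke_and_reproducible(self, small_population):
        kw = dict(methods=("EE",), criteria=("IE",), replications=2, seed=7)
        rs1 = run_condition(small_population, "eg", "PTPG", 200, 30, **kw)
        rs2 = run_condition(small_population, "eg", "PTPG", 200, 30, **kw)
        assert rs1.methods["EE"].shape == (2, 31)
        assert np.array_equal(rs1.methods["EE"], rs2.methods["EE"])

    def test_irt_sim_method_runs(self, small_population):
        rs = run_condition(small_population, "eg", "IRT", 200, 30,
                           methods=("EE",), criteria=("IE",),
                           replications=2, seed=3)
        assert rs.methods["EE"].shape == (2, 31)

    def test_neat_replication_produces_all_methods(self, small_population):
        cond = ConditionSpec("EE", 200, 30, "PTPG", "IE", "neat")
        res = run_replication(cond, small_population,
                              np.random.default_rng(4),
                              methods=("EE", "IRT", "KE", "IRTKE"))
        assert set(res.methods) == {"EE", "IRT", "KE", "IRTKE"}
        for arr in res.methods.values():
            assert np.all(np.diff(arr) >= -1e-8)
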