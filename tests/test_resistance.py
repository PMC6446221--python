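"""Scoring, ranking, rank-variability and parameter-influence contracts."""

import numpy as np
import pandas as pd
import pytest

from stressgwas import resistance
from stressgwas.resistance import (WeightVector, condition_scores,
                                   integrate_levels, orient_and_normalize,
                                   parameter_influence, performance_level,
                                   pi_correlation, rank_condition,
                                   rank_variability, ranking_table,
                                   robustness_strain, top_frequency)

from conftest import make_param_table


class TestWeights:
    def test_normalized_on_construction(self):
        w = WeightVector((2, 2, 2, 2, 2))
        assert sum(w.w) == pytest.approx(1.0)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            WeightVector((-1, 1, 1, 1, 1))


class TestOrientNormalize:
    def test_single_grower_beats_nongrower(self):
        table = make_param_table(
            {"A": {0: {"mu_max": 0.5}},
             "B": {0: {"mu_max": 0.0, "grew": False}}}
        )
        o = orient_and_normalize(table[table["level"] == 0])
        assert (o.loc["A"] == 1.0).all()
        assert (o.loc["B"] == 0.0).all()

    def test_identical_strains_get_half(self):
        table = make_param_table({"A": {0: {}}, "B": {0: {}}, "C": {0: {}}})
        o = orient_and_normalize(table)
        assert (o == 0.5).all().all()

    def test_time_like_inverted(self):
        table = make_param_table({"A": {0: {"lag_h": 2.0}},
                                  "B": {0: {"lag_h": 4.0}}})
        o = orient_and_normalize(table)
        assert o.loc["A", "lag_h"] == 1.0
        assert o.loc["B", "lag_h"] == 0.0

    def test_all_nongrowing_unusable(self):
        table = make_param_table({"A": {0: {"grew": False}},
                                  "B": {0: {"grew": False}}})
        assert orient_and_normalize(table) is None


class TestPerformance:
    def test_dominant_strain_has_unique_max(self):
        table = make_param_table(
            {"A": {0: {"mu_max": 0.9, "amplitude": 2.0, "lag_h": 1.0,
                       "t_half": 5.0, "auc": 90.0}},
             "B": {0: {}}, "C": {0: {"mu_max": 0.2}}}
        )
        o = orient_and_normalize(table)
        perf = performance_level(o, WeightVector())
        assert perf.idxmax() == "A"
        assert perf["A"] > perf.drop("A").max()

    def test_degenerate_weights_follow_single_parameter(self):
        table = make_param_table(
            {"A": {0: {"mu_max": 0.3}}, "B": {0: {"mu_max": 0.6}},
             "C": {0: {"mu_max": 0.45}}}
        )
        o = orient_and_normalize(table)
        w = WeightVector((0, 1, 0, 0, 0))  # order: lag, mu, amp, t_half, auc
        perf = performance_level(o, w)
        assert list(perf.sort_values(ascending=False).index) == ["B", "C", "A"]

    def test_swapped_profiles_equal_under_symmetric_weights(self):
        table = make_param_table(
            {"A": {0: {"mu_max": 0.3, "amplitude": 1.4}},
             "B": {0: {"mu_max": 0.6, "amplitude": 0.7}}}
        )
        o = orient_and_normalize(table)
        w = WeightVector((0, 0.5, 0.5, 0, 0))
        perf = performance_level(o, w)
        assert perf["A"] == pytest.approx(perf["B"])


class TestRobustness:
    def test_level_invariant_strain_scores_one(self):
        table = make_param_table({"A": {0: {}, 1: {}, 2: {}},
                                  "B": {0: {}, 1: {"mu_max": 0.1}, 2: {"mu_max": 0.05}}})
        rob = robustness_strain(table, "C1", WeightVector())
        assert rob["A"] == pytest.approx(1.0)

    def test_reference_only_grower_scores_zero(self):
        table = make_param_table(
            {"A": {0: {}, 1: {"grew": False}, 2: {"grew": False}}}
        )
        rob = robustness_strain(table, "C1", WeightVector())
        assert rob["A"] == pytest.approx(0.0)

    def test_absent_at_reference_is_missing(self):
        table = make_param_table({"A": {0: {"grew": False}, 1: {}},
                                  "B": {0: {}, 1: {}}})
        rob = robustness_strain(table, "C1", WeightVector())
        assert np.isnan(rob["A"])
        assert rob["B"] == pytest.approx(1.0)

    def test_performance_robustness_tradeoff_patterns(self):
        # strong grower collapsing at the top dose vs weak but stable grower
        def strong(scale):
            return {"mu_max": 0.8 * scale, "amplitude": 1.6 * scale,
                    "lag_h": 1.5 / scale, "t_half": 6.0 / scale,
                    "auc": 90.0 * scale}

        sprinter = {0: strong(1.0), 1: strong(0.9), 2: strong(0.75),
                    3: {"grew": False, "mu_max": 0.0, "amplitude": 0.0}}
        steady = {l: {"mu_max": 0.25, "amplitude": 0.55, "lag_h": 5.0,
                      "t_half": 18.0, "auc": 28.0} for l in range(4)}
        filler = {0: {"mu_max": 0.4, "amplitude": 0.9},
                  1: {"mu_max": 0.3, "amplitude": 0.7},
                  2: {"mu_max": 0.2, "amplitude": 0.5},
                  3: {"grew": False, "mu_max": 0.0, "amplitude": 0.0}}
        table = make_param_table({"sprinter": sprinter, "steady": steady,
                                  "mid": filler})
        sc = condition_scores(table, "C1")
        assert sc.loc["sprinter", "performance"] > sc.loc["steady", "performance"]
        assert sc.loc["steady", "robustness"] > sc.loc["sprinter", "robustness"]


class TestIntegrationAndRanking:
    def test_single_level_identity(self):
        s = pd.Series({"A": 0.7, "B": 0.2})
        out = integrate_levels({0: s})
        pd.testing.assert_series_equal(out, s, check_names=False)

    def test_equal_levels_unchanged(self):
        s = pd.Series({"A": 0.7, "B": 0.2})
        out = integrate_levels({0: s, 1: s.copy(), 2: s.copy()})
        pd.testing.assert_series_equal(out, s, check_names=False)

    def test_tie_ranks_average(self):
        scores = pd.Series({"A": 0.9, "B": 0.5, "C": 0.5, "D": 0.1})
        rk = rank_condition(scores)
        assert rk.loc["A", "rank"] == 1
        assert rk.loc["B", "rank"] == rk.loc["C", "rank"] == 2.5
        assert rk.loc["D", "rank"] == 4

    def test_decile_ranking_value(self):
        scores = pd.Series(np.linspace(1, 0, 36),
                           index=[f"S{i}" for i in range(36)])
        rk = rank_condition(scores)
        # rank 22 of 36 -> ceil(220/36) = 7, a "low" ranking value (>6)
        assert rk.loc["S21", "rank"] == 22
        assert rk.loc["S21", "ranking_value"] == 7

    def test_all_equal_same_ranking_value(self):
        rk = rank_condition(pd.Series({"A": 0.5, "B": 0.5, "C": 0.5}))
        assert rk["ranking_value"].nunique() == 1

    def test_missing_ranked_last(self):
        rk = rank_condition(pd.Series({"A": 0.9, "B": np.nan, "C": 0.1}))
        assert rk.loc["B", "rank"] == 3

    def test_monotone_rescaling_invariance(self):
        values = {s: {l: {"mu_max": 0.2 + 0.1 * i, "amplitude": 0.5 + 0.2 * i}
                      for l in range(3)}
                  for i, s in enumerate("ABCD")}
        table = make_param_table(values)
        scaled = table.copy()
        for k in ("mu_max", "amplitude", "auc"):
            scaled[k] = scaled[k] * 3.0
        a = rank_condition(condition_scores(table, "C1")["performance"])
        b = rank_condition(condition_scores(scaled, "C1")["performance"])
        pd.testing.assert_series_equal(a["rank"], b["rank"])


class TestTopFrequency:
    def test_always_first_counts_everywhere(self):
        # strain A is both the best performer and perfectly level-stable;
        # the others degrade with level, so A is rank 1 in every ranking
        values = {
            s: {l: {"mu_max": (0.6 - 0.1 * i) * (1.0 - 0.15 * i * l)}
                for l in range(2)}
            for i, s in enumerate("ABCD")
        }
        table = make_param_table(values, conditions=("C1", "C2", "C3"))
        rankings = ranking_table(table)
        freq = top_frequency(rankings, k=1)
        assert freq["A"] == 2 * 3  # both score types, every condition

    def test_k_equals_n_counts_all(self):
        values = {s: {l: {"mu_max": 0.6 - 0.1 * i} for l in range(2)}
                  for i, s in enumerate("ABCD")}
        table = make_param_table(values)
        rankings = ranking_table(table)
        freq = top_frequency(rankings, k=4)
        assert (freq == 2).all()


class TestRVA:
    def _table(self):
        return make_param_table(
            {"dom": {l: {"mu_max": 0.9, "amplitude": 2.0, "lag_h": 1.0,
                         "t_half": 5.0, "auc": 90.0} for l in range(2)},
             "twin1": {l: {"mu_max": 0.3} for l in range(2)},
             "twin2": {l: {"mu_max": 0.3} for l in range(2)},
             "weak": {l: {"mu_max": 0.1, "amplitude": 0.4} for l in range(2)}}
        )

    def test_dominant_strain_rank_one_always(self):
        rva = rank_variability(self._table(), "C1", n_weight_samples=50, seed=1)
        assert rva.loc["dom", "q05"] == rva.loc["dom", "q95"] == 1.0
        # rank 1 of 4 strains falls in decile bin ceil(10/4) = 3
        assert rva.loc["dom", "bin_3"] == 1.0

    def test_identical_strains_identical_distributions(self):
        rva = rank_variability(self._table(), "C1", n_weight_samples=50, seed=1)
        pd.testing.assert_series_equal(
            rva.loc["twin1"], rva.loc["twin2"], check_names=False
        )

    def test_equal_weight_score_equals_mean_of_sampled_scores(self):
        # E[w] over Dirichlet(1,...,1) is the equal-weight vector
        table = self._table()
        rng = np.random.default_rng(5)
        samples = rng.dirichlet(np.ones(5), size=800)
        perf = [condition_scores(table, "C1", WeightVector(w))["performance"]
                for w in samples]
        mean_sampled = pd.concat(perf, axis=1).mean(axis=1)
        equal = condition_scores(table, "C1", WeightVector())["performance"]
        pd.testing.assert_series_equal(mean_sampled, equal, atol=0.02,
                                       check_names=False)

    def test_weight_specific_rank_convergence_exists(self):
        # strains with different growth profiles can land on close ranks
        # under particular weightings
        table = make_param_table(
            {"A": {0: {"mu_max": 0.8, "amplitude": 0.5}},
             "B": {0: {"mu_max": 0.2, "amplitude": 1.8}},
             "C": {0: {"mu_max": 0.5, "amplitude": 1.0}}}
        )
        mu_only = rank_condition(
            condition_scores(table, "C1", WeightVector((0, 1, 0, 0, 0)))
            ["performance"])["rank"]
        amp_only = rank_condition(
            condition_scores(table, "C1", WeightVector((0, 0, 1, 0, 0)))
            ["performance"])["rank"]
        balanced = rank_condition(
            condition_scores(table, "C1",
                             WeightVector((0, 0.5, 0.5, 0, 0)))
            ["performance"])["rank"]
        assert mu_only["A"] != amp_only["A"]
        assert balanced["A"] == balanced["B"]


class TestPI:
    def test_all_identical_all_zero(self):
        table = make_param_table({"A": {0: {}}, "B": {0: {}}, "C": {0: {}}})
        pi = parameter_influence(table)
        assert (pi.to_numpy() == 0).all()

    def test_best_on_one_parameter_positive_pi(self):
        table = make_param_table(
            {"A": {0: {"mu_max": 0.9, "amplitude": 0.5, "auc": 20.0}},
             "B": {0: {"mu_max": 0.3, "amplitude": 1.5, "auc": 60.0}},
             "C": {0: {"mu_max": 0.3, "amplitude": 1.5, "auc": 60.0}}}
        )
        pi = parameter_influence(table, bump=1.0)
        assert pi.loc["A", ("C1", "mu_max")] > 0

    def test_normalization_fixpoint(self):
        table = make_param_table(
            {"A": {0: {"mu_max": 0.9, "amplitude": 0.5}},
             "B": {0: {"mu_max": 0.3, "amplitude": 1.5}},
             "C": {0: {"mu_max": 0.5, "amplitude": 1.0}}}
        )
        pi = parameter_influence(table, bump=1.0)
        m = np.abs(pi.to_numpy())
        assert np.nanmax(m) == pytest.approx(1.0)
        assert np.nanmin(pi.to_numpy()) >= -1.0 and np.nanmax(pi.to_numpy()) <= 1.0

    def test_bump_must_be_positive(self):
        with pytest.raises(ValueError):
            parameter_influence(make_param_table({"A": {0: {}}, "B": {0: {}}}),
                                bump=0.0)


class TestPICorrelation:
    def _pi(self):
        idx = ["A", "B", "C"]
        cols = pd.MultiIndex.from_product([["C1", "C2"], ["mu_max", "lag_h"]],
                                          names=["condition", "parameter"])
        data = np.array([[1.0, -0.5, 0.25, -1.0],
                         [-1.0, 0.5, -0.25, 1.0],
                         [0.1, 0.3, -0.2, 0.4]])
        return pd.DataFrame(data, index=idx, columns=cols)

    def test_self_correlation_is_one(self):
        rho, p = pi_correlation(self._pi(), "A", "A")
        assert rho == pytest.approx(1.0)

    def test_mirrored_profiles_minus_one(self):
        rho, p = pi_correlation(self._pi(), "A", "B")
        assert rho == pytest.approx(-1.0)

    def test_constant_profile_missing(self):
        pi = self._pi()
        pi.loc["C"] = 0.0
        rho, p = pi_correlation(pi, "A", "C")
        assert np.isnan(rho) and np.isnan(p)

    def test_independent_profiles_calibrated(self, rng):
        # random independent profiles: p roughly uniform
        cols = pd.MultiIndex.from_product(
            [[f"C{i}" for i in range(6)], ["a", "b", "c", "d", "e"]])
        ps = []
        for _ in range(200):
            pi = pd.DataFrame(rng.normal(size=(2, 30)), index=["A", "B"],
                              columns=cols)
            ps.append(pi_correlation(pi, "A", "B")[1])
        assert 0.01 < np.mean(np.asarray(ps) < 0.05) < 0.12
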