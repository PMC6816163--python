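"""Information criteria, repetition summaries, and model ranking."""

import math

import numpy as np
import pytest

import moietykit as mk
from moietykit import analysis as ana
from moietykit import simulate as sim


class TestRss:
    def test_zero_for_identical(self):
        p = mk.IsotopologueProfile("m", ("13C",), ((0,), (1,)), np.array([0.2, 0.8]))
        assert ana.rss(p, p) == 0.0

    def test_direct_arithmetic(self):
        o = mk.IsotopologueProfile("m", ("13C",), ((0,), (1,)), np.array([0.2, 0.8]))
        c = mk.IsotopologueProfile("m", ("13C",), ((0,), (1,)), np.array([0.1, 0.9]))
        assert ana.rss(o, c) == pytest.approx(0.02)

    def test_sums_over_multiple_datasets_order_free(self):
        o1 = mk.IsotopologueProfile("m", ("13C",), ((0,), (1,)), np.array([0.2, 0.8]))
        c1 = mk.IsotopologueProfile("m", ("13C",), ((0,), (1,)), np.array([0.1, 0.9]))
        o2 = mk.IsotopologueProfile("m", ("13C",), ((0,), (1,)), np.array([0.5, 0.5]))
        c2 = mk.IsotopologueProfile("m", ("13C",), ((0,), (1,)), np.array([0.4, 0.6]))
        assert ana.rss([o1, o2], [c1, c2]) == pytest.approx(ana.rss([o2, o1], [c2, c1]))


class TestInformationCriteria:
    def test_aic_reduces_to_2k_when_rss_equals_n(self):
        crit = ana.information_criteria(k=6, n=54, rss_value=54.0)
        assert crit["AIC"] == pytest.approx(12.0)

    def test_aicc_small_sample_correction(self):
        crit = ana.information_criteria(k=6, n=54, rss_value=54.0)
        assert crit["AICc"] == pytest.approx(12.0 + 84.0 / 47.0)
        assert crit["AICc"] == pytest.approx(13.7872, abs=1e-4)

    def test_bic_closed_form(self):
        crit = ana.information_criteria(k=6, n=54, rss_value=54.0)
        assert crit["BIC"] == pytest.approx(6 * math.log(54))
        assert crit["BIC"] == pytest.approx(23.934, abs=1e-3)

    def test_consistency_of_all_three_forms(self):
        k, n, r = 4, 30, 0.37
        crit = ana.information_criteria(k, n, r)
        log_term = n * math.log(r / n)
        assert crit["AIC"] == pytest.approx(2 * k + log_term)
        assert crit["AICc"] == pytest.approx(crit["AIC"] + (2 * k * k + 2 * k) / (n - k - 1))
        assert crit["BIC"] == pytest.approx(log_term + k * math.log(n))

    def test_zero_rss_gives_sentinel_with_warning(self):
        with pytest.warns(UserWarning, match="perfect fit"):
            crit = ana.information_criteria(k=2, n=10, rss_value=0.0)
        assert crit["AIC"] == float("-inf")
        assert crit["BIC"] == float("-inf")

    def test_aicc_undefined_for_small_n(self):
        crit = ana.information_criteria(k=6, n=7, rss_value=1.0)
        assert crit["AICc"] is None
        assert crit["AIC"] is not None

    def test_each_criterion_increases_with_rss(self):
        k, n = 5, 40
        lo = ana.information_criteria(k, n, 0.1)
        hi = ana.information_criteria(k, n, 0.2)
        for key in ("AIC", "AICc", "BIC"):
            assert hi[key] > lo[key]

    def test_aicc_exceeds_aic_for_positive_k(self):
        for k in (1, 3, 9):
            crit = ana.information_criteria(k, 30, 0.5)
            assert crit["AICc"] > crit["AIC"]


def _noiseless_result(model, truth, repetitions=3, step_number=300, polish=True):
    base = mk.calc_intensity_profile(model.molecules[0], truth)
    ds = sim.profile_to_dataset(base, "d")
    settings = mk.OptimizationSettings(
        saga=mk.SagaSettings(step_number=step_number),
        repetitions=repetitions, seed=5, polish=polish,
        objective=mk.ObjectiveSpec("square_difference"),
    )
    return mk.optimize(model, [ds], settings), [ds]


class TestSummarizeRepetitions:
    def test_single_repetition_stats_collapse(self, expert_single):
        model, truth = expert_single
        result, datasets = _noiseless_result(model, truth, repetitions=1)
        analysis = ana.summarize_repetitions(result, model, datasets)
        for stats in analysis.parameter_stats.values():
            for p in stats:
                assert p.sd == 0.0
                assert p.min == p.max == pytest.approx(p.mean)

    def test_identical_repetitions_have_zero_sd(self, expert_single):
        model, truth = expert_single
        result, datasets = _noiseless_result(model, truth, repetitions=1)
        rep = result.blocks["d"][0]
        result.blocks["d"] = [rep, rep, rep]
        analysis = ana.summarize_repetitions(result, model, datasets)
        for p in analysis.parameter_stats["d"]:
            assert p.sd == pytest.approx(0.0, abs=1e-14)

    def test_noiseless_recovery_has_tiny_rss(self, expert_single):
        model, truth = expert_single
        result, datasets = _noiseless_result(model, truth, repetitions=3)
        analysis = ana.summarize_repetitions(result, model, datasets)
        assert analysis.rss < 1e-6
        assert analysis.n == 18
        assert analysis.k == model.free_parameter_count

    def test_split_k_convention_counts_all_blocks(self, expert_single):
        model, truth = expert_single
        base = mk.calc_intensity_profile(model.molecules[0], truth)
        datasets = [sim.profile_to_dataset(base, f"t{i}") for i in range(3)]
        settings = mk.OptimizationSettings(
            saga=mk.SagaSettings(step_number=100), repetitions=1, seed=0
        )
        result = mk.optimize(model, datasets, settings)
        per_ds = ana.summarize_repetitions(result, model, datasets, k_convention="per_dataset")
        per_model = ana.summarize_repetitions(result, model, datasets, k_convention="model")
        assert per_ds.k == 3 * model.free_parameter_count
        assert per_model.k == model.free_parameter_count
        assert per_ds.n == per_model.n == 54

    def test_empty_result_rejected(self, expert_single):
        model, truth = expert_single
        result, datasets = _noiseless_result(model, truth, repetitions=1)
        result.blocks = {}
        with pytest.raises(ValueError):
            ana.summarize_repetitions(result, model, datasets)


class TestRankModels:
    @staticmethod
    def _analysis(name, aicc):
        return ana.ModelAnalysis(
            model_name=name, k=6, n=54, rss=0.01,
            aic=aicc - 1, aicc=aicc, bic=aicc + 1,
        )

    def test_lower_aicc_ranks_first(self):
        table = ana.rank_models(
            [self._analysis("variant", -227.5208), self._analysis("expert", -229.2918)],
            criterion="AICc",
        )
        assert list(table["model"]) == ["expert", "variant"]
        assert table.iloc[0]["value"] == pytest.approx(-229.2918)

    def test_single_model_ranks_itself(self):
        table = ana.rank_models([self._analysis("only", 1.0)])
        assert list(table["model"]) == ["only"]

    def test_exact_ties_break_lexicographically(self):
        table = ana.rank_models(
            [self._analysis("zeta", 5.0), self._analysis("alpha", 5.0)]
        )
        assert list(table["model"]) == ["alpha", "zeta"]

    def test_undefined_criterion_ranks_last_with_flag(self):
        defined = self._analysis("ok", 3.0)
        undefined = ana.ModelAnalysis(
            model_name="undef", k=20, n=21, rss=0.01, aic=1.0, aicc=None, bic=2.0
        )
        table = ana.rank_models([undefined, defined], criterion="AICc")
        assert list(table["model"]) == ["ok", "undef"]
        assert not table.iloc[1]["defined"]

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            ana.rank_models([self._analysis("m", 1.0)], criterion="DIC")


class TestComparisonTable:
    def test_ranks_across_settings(self):
        a = ana.rank_models(
            [TestRankModels._analysis("m1", 1.0), TestRankModels._analysis("m2", 2.0)]
        )
        b = ana.rank_models(
            [TestRankModels._analysis("m1", 9.0), TestRankModels._analysis("m2", 2.0)]
        )
        table = ana.comparison_table({"log": a, "abs": b})
        assert table.loc["m1", "log"] == 1
        assert table.loc["m1", "abs"] == 2
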