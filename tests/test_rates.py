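import numpy as np
import pytest
from scipy import stats as st

from evotraj import presets
from evotraj.rates import (
    RankDeficientDesignError,
    RatePoint,
    build_rate_points,
    compare_rates_ftest,
    fit_multirate,
    fit_single_rate,
    fold_change,
    generation_time,
    normalize_lineage_fractions,
)


def points_from(g, m, fractions=None, labels=None):
    g = np.asarray(g, dtype=float)
    m = np.asarray(m, dtype=float)
    out = []
    for i in range(len(g)):
        fr = (
            {lab: fractions[lab][i] for lab in labels}
            if fractions
            else {}
        )
        out.append(RatePoint(f"s{i}", g[i], m[i], fr))
    return out


class TestNormalizeLineageFractions:
    def test_overfull_markers_rescaled_proportionally(self):
        fa, fd, anc = normalize_lineage_fractions(0.6, 0.5)
        assert fa == pytest.approx(6 / 11)
        assert fd == pytest.approx(5 / 11)
        assert anc == 0.0

    def test_remainder_is_ancestral(self):
        assert normalize_lineage_fractions(0.2, 0.3) == (0.2, 0.3, 0.5)

    def test_pure_nonmutator(self):
        assert normalize_lineage_fractions(0.0, 0.0) == (0.0, 0.0, 1.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_lineage_fractions(-0.1, 0.2)


class TestFitSingleRate:
    def test_closed_form_example(self):
        fit = fit_single_rate(points_from([10, 20], [1.0, 2.2]))
        assert fit.rates[0] == pytest.approx(0.108)
        assert fit.standard_errors[0] == pytest.approx(0.004)

    def test_exact_recovery_on_consistent_data(self):
        g = np.array(presets.FLY_GENERATIONS)
        fit = fit_single_rate(points_from(g, 0.00177 * g))
        assert fit.rates[0] == pytest.approx(0.00177, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_zero_frequencies_give_zero_rate(self):
        fit = fit_single_rate(points_from([10, 20, 30], [0, 0, 0]))
        assert fit.rates[0] == 0.0

    def test_all_zero_generations_rejected(self):
        with pytest.raises(ValueError):
            fit_single_rate(points_from([0.0, 0.0], [0.1, 0.2]))

    def test_single_point_has_no_standard_error(self):
        fit = fit_single_rate(points_from([10.0], [1.0]))
        assert fit.standard_errors is None


class TestFitMultirate:
    def test_one_hot_fractions_reduce_to_per_lineage_fits(self):
        g = [10.0, 20.0, 30.0, 40.0]
        fr = {"a": [1, 1, 0, 0], "b": [0, 0, 1, 1]}
        m = [0.5, 1.1, 2.9, 4.1]
        fit = fit_multirate(points_from(g, m, fr, ["a", "b"]), ("a", "b"))
        fit_a = fit_single_rate(points_from(g[:2], m[:2]))
        fit_b = fit_single_rate(points_from(g[2:], m[2:]))
        assert fit.rate("a") == pytest.approx(fit_a.rates[0])
        assert fit.rate("b") == pytest.approx(fit_b.rates[0])

    def test_noise_free_three_lineage_recovery(self):
        g = np.array(presets.MOUSE_HOST_GENERATIONS)
        fr = {
            "ancestral": np.array(presets.ANCESTRAL_FRACTIONS),
            "mutS_A41T": np.array(presets.A41T_FRACTIONS),
            "mutS_D1303": np.array(presets.D1303_FRACTIONS),
        }
        true = {"ancestral": 0.0076, "mutS_A41T": 2.453, "mutS_D1303": 0.310}
        m = sum(true[k] * fr[k] * g for k in true)
        fit = fit_multirate(
            points_from(g, m, fr, list(true)), tuple(true)
        )
        for k, r in true.items():
            assert fit.rate(k) == pytest.approx(r, rel=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_duplicate_lineage_columns_rejected(self):
        g = [10.0, 20.0, 30.0]
        fr = {"a": [0.5, 0.6, 0.7], "b": [0.5, 0.6, 0.7]}
        with pytest.raises(RankDeficientDesignError):
            fit_multirate(points_from(g, [1, 2, 3], fr, ["a", "b"]), ("a", "b"))

    def test_absent_lineage_named_in_error(self):
        g = [10.0, 20.0, 30.0]
        fr = {"a": [0.5, 0.6, 0.7], "ghost": [0.0, 0.0, 0.0]}
        with pytest.raises(RankDeficientDesignError, match="ghost"):
            fit_multirate(
                points_from(g, [1, 2, 3], fr, ["a", "ghost"]), ("a", "ghost")
            )

    def test_single_lineage_identical_to_single_rate_fit(self):
        g = [10.0, 25.0, 40.0, 70.0]
        m = [1.2, 2.3, 4.9, 7.0]
        fr = {"only": [1.0] * 4}
        multi = fit_multirate(points_from(g, m, fr, ["only"]), ("only",))
        single = fit_single_rate(points_from(g, m))
        assert multi.rates[0] == pytest.approx(single.rates[0], rel=1e-14)
        assert multi.standard_errors[0] == pytest.approx(
            single.standard_errors[0], rel=1e-12
        )

    def test_scale_equivariance_in_generations(self):
        g = np.array([10.0, 20.0, 35.0, 50.0])
        m = np.array([0.9, 2.1, 3.4, 5.2])
        fit1 = fit_single_rate(points_from(g, m))
        fit2 = fit_single_rate(points_from(3.0 * g, m))
        assert fit2.rates[0] == pytest.approx(fit1.rates[0] / 3.0, rel=1e-12)


class TestCompareRatesFtest:
    def test_null_pvalues_are_uniform(self):
        # equal true rates + gaussian noise: p should be Uniform(0, 1)
        rng = np.random.default_rng(7)
        g = np.array([30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 240.0])
        fa = np.array([0.2, 0.4, 0.6, 0.5, 0.3, 0.7, 0.6, 0.4])
        fr = {"a": fa, "b": 1 - fa}
        pvals = []
        for _ in range(300):
            m = 0.05 * fa * g + 0.05 * (1 - fa) * g + rng.normal(0, 0.3, len(g))
            cmp_result = compare_rates_ftest(
                points_from(g, m, fr, ["a", "b"]), ("a", "b"), ("a", "b")
            )
            pvals.append(cmp_result.p_value)
        assert st.kstest(pvals, "uniform").pvalue > 1e-3

    def test_noise_free_unequal_rates_take_degenerate_path(self):
        g = np.array([10.0, 20.0, 30.0, 40.0])
        fa = np.array([0.3, 0.5, 0.6, 0.4])
        fr = {"a": fa, "b": 1 - fa}
        m = 2.0 * fa * g + 0.5 * (1 - fa) * g
        with pytest.warns(UserWarning, match="degenerate"):
            cmp_result = compare_rates_ftest(
                points_from(g, m, fr, ["a", "b"]), ("a", "b"), ("a", "b")
            )
        assert cmp_result.degenerate
        assert np.isinf(cmp_result.f_statistic)
        assert cmp_result.p_value == 0.0

    def test_single_lineage_model_has_nothing_to_compare(self):
        pts = points_from([10.0, 20.0], [1.0, 2.0], {"a": [1, 1]}, ["a"])
        with pytest.raises(ValueError):
            compare_rates_ftest(pts, ("a",), ("a", "a"))


class TestFoldChangeAndGenerationTime:
    def test_reported_fold_factors(self):
        assert fold_change(2.453, 0.0076, rounded=True) == 323
        assert fold_change(0.310, 0.0076, rounded=True) == 41
        assert fold_change(0.5, 0.5) == 1.0

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)

    def test_one_doubling_takes_the_whole_interval(self):
        assert generation_time(0.0, 7.0, 1e5, 2e5) == pytest.approx(7.0)

    def test_thousandfold_growth(self):
        assert generation_time(0.0, 3.0, 1e3, 1e6) == pytest.approx(0.30103, abs=1e-5)

    def test_two_doublings_halve_the_time(self):
        assert generation_time(0.0, 8.0, 1e4, 4e4) == pytest.approx(4.0)

    def test_decline_warns_and_returns_negative(self):
        with pytest.warns(UserWarning, match="declined"):
            assert generation_time(0.0, 2.0, 1e6, 1e5) < 0

    def test_zero_growth_rejected(self):
        with pytest.raises(ValueError):
            generation_time(0.0, 2.0, 1e5, 1e5)


def test_build_rate_points_normalizes_two_marker_design():
    pts = build_rate_points(
        ["s0"], [100.0], [1.0],
        {"A": np.array([0.6]), "B": np.array([0.5])},
    )
    fr = pts[0].fractions
    assert fr["A"] == pytest.approx(6 / 11)
    assert fr["B"] == pytest.approx(5 / 11)
    assert fr["ancestral"] == 0.0
    assert sum(fr.values()) == pytest.approx(1.0)
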