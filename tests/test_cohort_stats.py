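"""Cohort statistics: Spearman, magnitude bands, Loess, agreement, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ironmri import (classify_magnitude, loess_smooth, method_agreement,
                     spearman, stratified_spearman, summarize_cohort)
from ironmri.cohort_stats import percentage, scatter_with_loess
from ironmri.exceptions import InsufficientDataError, InvalidInputError

from conftest import brute_spearman


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x)).r == pytest.approx(1.0)
        assert spearman(x, -x**3).r == pytest.approx(-1.0)

    def test_ties_match_hand_ranked_oracle(self):
        x = [1, 2, 2, 4]
        y = [3, 1, 4, 4]
        res = spearman(x, y)
        assert res.r == pytest.approx(brute_spearman(x, y), abs=1e-12)
        assert res.r == pytest.approx(0.5, abs=1e-12)

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            x = rng.integers(0, 6, n).astype(float)  # heavy ties
            y = rng.integers(0, 6, n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue  # correlation undefined for a constant vector
            assert spearman(x, y).r == pytest.approx(
                brute_spearman(x, y), abs=1e-12)

    @given(st.lists(st.integers(-1000, 1000), min_size=5, max_size=20,
                    unique=True),
           st.lists(st.integers(-1000, 1000), min_size=5, max_size=20,
                    unique=True))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_invariant_under_monotone_transform(self, xs, ys):
        # values on a coarse grid so cubing cannot underflow into ties
        n = min(len(xs), len(ys))
        x = np.array(xs[:n], dtype=float) * 0.1
        y = np.array(ys[:n], dtype=float) * 0.1
        r0 = spearman(x, y).r
        r1 = spearman(np.exp(x / 100), y**3).r
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_pairwise_deletion_of_missing(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, np.nan, 10.0]
        res = spearman(x, y)
        assert res.n == 3
        assert res.r == pytest.approx(1.0)

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            spearman([1.0, np.nan, 3.0], [1.0, 2.0, np.nan])

    def test_exact_permutation_p_small_n(self):
        # perfectly monotone n=4: only 2 of 4! pairings reach |r| = 1
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40], exact=True)
        assert res.p_value == pytest.approx(2 / 24)
        with pytest.raises(InvalidInputError):
            spearman(np.arange(11), np.arange(11), exact=True)


class TestMagnitude:
    @pytest.mark.parametrize("r,label", [
        (0.504, "moderate"),   # published pancreas-heart correlation
        (0.595, "moderate"),   # liver online-vs-pixel, band edge inclusive
        (0.782, "strong"),     # heart online-vs-pixel
        (0.270, "weak"),       # pancreas-liver
        (-0.734, "strong"),    # ferritin-liver (magnitude uses |r|)
        (0.4, "moderate"),
        (0.6, "moderate"),
        (0.0, "weak"),
        (1.0, "strong"),
    ])
    def test_bands(self, r, label):
        assert classify_magnitude(r) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_magnitude(1.2)


class TestLoess:
    def test_collinear_points_reproduced_exactly(self):
        x = np.linspace(0, 10, 20)
        y = 3.0 * x - 2.0
        xs, fitted = loess_smooth(x, y, span=0.5)
        assert np.max(np.abs(fitted - (3.0 * xs - 2.0))) < 1e-8

    def test_duplicated_dataset_same_curve(self):
        rng = np.random.default_rng(4)
        x = np.sort(rng.uniform(0, 10, 16))
        y = np.sin(x) + rng.normal(0, 0.1, 16)
        xs1, f1 = loess_smooth(x, y, span=0.5)
        xs2, f2 = loess_smooth(np.r_[x, x], np.r_[y, y], span=0.5)
        assert np.allclose(np.unique(xs2), xs1)
        assert np.allclose(f2[::2], f1) and np.allclose(f2[1::2], f1)

    def test_matches_reference_lowess(self):
        # independent cross-implementation check
        from statsmodels.nonparametric.smoothers_lowess import lowess

        rng = np.random.default_rng(5)
        for span in (0.3, 0.5, 0.75):
            x = rng.uniform(0, 10, 60)
            y = np.cos(x) + rng.normal(0, 0.3, 60)
            xs, fitted = loess_smooth(x, y, span=span)
            ref = lowess(y, x, frac=span, it=0, return_sorted=True)
            assert np.max(np.abs(fitted - ref[:, 1])) < 1e-6

    def test_preconditions(self):
        with pytest.raises(InsufficientDataError):
            loess_smooth([1, 2, 3, 4], [1, 2, 3, 4])
        with pytest.raises(InvalidInputError):
            loess_smooth(np.arange(10.0), np.arange(10.0), span=1.5)
        with pytest.raises(InsufficientDataError):
            loess_smooth(np.arange(10.0), np.arange(10.0), span=0.1)

    def test_scatter_plot_smoke(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 40, 30)
        ax = scatter_with_loess(x, x + rng.normal(0, 3, 30),
                                xlabel="pancreas T2*", ylabel="heart T2*")
        assert ax.get_xlabel() == "pancreas T2*"


class TestMethodAgreement:
    def test_identical_methods(self):
        res = method_agreement([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_difference == 0 and res.ci_low == res.ci_high == 0

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0])
        res = method_agreement(a, a + 3)
        assert res.mean_difference == pytest.approx(-3.0)
        assert res.ci_low == res.ci_high == pytest.approx(-3.0)

    def test_hand_computed_three_point_ci(self):
        # d = (1, 2, 0): mean 1, SD 1, SE 1/sqrt(3),
        # t_{0.975,2} = 4.302652729749462 -> half-width 2.4841377117503303
        res = method_agreement([5.0, 7.0, 9.0], [4.0, 5.0, 9.0])
        assert res.mean_difference == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0 - 2.4841377117503303, abs=1e-9)
        assert res.ci_high == pytest.approx(1.0 + 2.4841377117503303, abs=1e-9)

    def test_ci_width_shrinks_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(7)
        widths = {}
        for n in (10, 100, 1000):
            d = rng.normal(1.0, 2.0, n)
            res = method_agreement(d, np.zeros(n))
            widths[n] = res.ci_high - res.ci_low
        slope = np.polyfit(np.log([10, 100, 1000]),
                           np.log([widths[n] for n in (10, 100, 1000)]), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            method_agreement([1.0], [2.0])


class TestSummarize:
    def test_percentage_rounding_half_away_from_zero(self):
        assert percentage(32, 39) == 82.1
        assert percentage(37, 39) == 94.9
        assert percentage(9, 39) == 23.1
        assert percentage(1, 8) == 12.5
        assert percentage(1, 16, ndigits=0) == 6.0  # 6.25 -> 6

    def test_single_patient(self):
        df = pd.DataFrame({"patient_id": ["P1"], "t2s_liver_ms": [4.2]})
        table = summarize_cohort(df)
        row = table.continuous.loc["t2s_liver_ms"]
        assert row["mean"] == row["median"] == 4.2
        assert row["sd"] == 0.0

    def test_hand_computed_moments(self):
        df = pd.DataFrame({"patient_id": list("abcd"),
                           "v": [1.0, 2.0, 3.0, 4.0]})
        row = summarize_cohort(df).continuous.loc["v"]
        assert row["mean"] == 2.5
        assert row["median"] == 2.5
        assert row["sd"] == pytest.approx(np.sqrt(5 / 3))  # n-1 denominator
        assert row["min"] == 1.0 and row["max"] == 4.0

    def test_categorical_counts_and_percentages(self):
        df = pd.DataFrame({"patient_id": [f"P{i}" for i in range(39)],
                           "grade": ["normal"] * 7 + ["abnormal"] * 32})
        cat = summarize_cohort(df).categorical.set_index("level")
        assert cat.loc["abnormal", "count"] == 32
        assert cat.loc["abnormal", "pct"] == 82.1
        assert cat.loc["normal", "pct"] == 17.9
        assert cat["count"].sum() == 39

    def test_empty_cohort_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_cohort(pd.DataFrame({"patient_id": []}))


class TestStratified:
    def test_single_stratum_equals_global(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 10, 20)
        y = x + rng.normal(0, 1, 20)
        strata = np.array(["all"] * 20)
        res = stratified_spearman(x, y, strata)
        assert res["all"].r == pytest.approx(spearman(x, y).r)

    def test_internally_monotone_strata(self):
        x = np.r_[np.arange(5.0), np.arange(5.0)]
        y = np.r_[np.arange(5.0) * 2, 100 - np.arange(5.0) ** 2]
        strata = np.array(["up"] * 5 + ["down"] * 5)
        res = stratified_spearman(x, y, strata)
        assert res["up"].r == pytest.approx(1.0)
        assert res["down"].r == pytest.approx(-1.0)

    def test_matches_per_stratum_bruteforce(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 8, 24).astype(float)
        y = rng.integers(0, 8, 24).astype(float)
        strata = np.repeat(["a", "b"], 12)
        res = stratified_spearman(x, y, strata)
        for label in ("a", "b"):
            sel = strata == label
            assert res[label].r == pytest.approx(
                brute_spearman(x[sel], y[sel]), abs=1e-12)

    def test_small_stratum_skipped(self):
        x = np.arange(6.0)
        y = np.arange(6.0)
        strata = np.array(["big"] * 4 + ["tiny"] * 2)
        res = stratified_spearman(x, y, strata)
        assert "big" in res and "tiny" not in res
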