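"""Large-EV statistics: filtering, histograms, Mann-Whitney, labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import mannwhitneyu

from conftest import mwu_oracle_p
from evchip.errors import StatisticsError
from evchip.sizestats import (
    classify_significance,
    compare_conditions,
    filter_levs,
    mann_whitney_u,
    size_histogram,
    window_difference,
)


def _particles(diameters, heights=None, ligand="L", condition="control"):
    d = np.asarray(diameters, dtype=float)
    h = np.asarray(heights, dtype=float) if heights is not None else 0.12 * d
    return pd.DataFrame(
        {
            "id": range(d.size),
            "source": "img",
            "ligand": ligand,
            "condition": condition,
            "max_diameter_nm": d,
            "height_nm": h,
            "area_nm2": np.pi * d**2 / 4,
            "centroid_x_nm": 0.0,
            "centroid_y_nm": 0.0,
            "pixel_count": 10,
            "touches_border": False,
        }
    )


class TestFilter:
    def test_strictly_greater_than_cut(self):
        out = filter_levs(_particles([150.0, 200.0, 201.0]))
        assert list(out["max_diameter_nm"]) == [201.0]

    def test_identity_when_all_large(self):
        table = _particles([250.0, 900.0])
        assert len(filter_levs(table)) == 2

    def test_empty_in_empty_out(self):
        assert len(filter_levs(_particles([]))) == 0


class TestHistogram:
    def test_single_bin_is_hundred_percent(self):
        dist = size_histogram(_particles([210.0, 250.0, 260.0, 299.0]))
        assert dist.percentages[0] == pytest.approx(100.0)
        assert sum(dist.counts) == 4

    def test_quarter_half_quarter(self):
        dist = size_histogram(_particles([250.0, 350.0, 350.0, 450.0]))
        assert dist.percentages[:3] == (
            pytest.approx(25.0), pytest.approx(50.0), pytest.approx(25.0)
        )

    def test_overflow_bin_catches_giants(self):
        dist = size_histogram(_particles([250.0, 1500.0]))
        assert dist.bin_labels[-1] == ">=1000"
        assert dist.counts[-1] == 1

    @given(
        st.lists(st.floats(200.001, 3000, allow_nan=False), min_size=1, max_size=60)
    )
    def test_percentages_sum_to_hundred(self, diameters):
        dist = size_histogram(_particles(diameters))
        assert sum(dist.percentages) == pytest.approx(100.0, abs=1e-9)
        assert sum(dist.counts) == len(diameters)


class TestWindowDifference:
    def test_identical_distributions_zero_difference(self):
        table = _particles([250.0, 450.0, 650.0, 850.0])
        out = window_difference(table, table.copy())
        assert np.allclose(out["difference"], 0.0)

    def test_sign_convention_positive_means_more_in_treated(self):
        control = _particles([250.0] * 60 + [450.0] * 40)
        treated = _particles([250.0] * 65 + [450.0] * 35, condition="treated")
        out = window_difference(control, treated).set_index("window")
        assert out.loc["200-400", "pct_control"] == pytest.approx(60.0)
        assert out.loc["200-400", "pct_treated"] == pytest.approx(65.0)
        assert out.loc["200-400", "difference"] == pytest.approx(5.0)
        assert out.loc["400-600", "difference"] == pytest.approx(-5.0)

    def test_zero_lev_condition_errors(self):
        with pytest.raises(StatisticsError, match="zero large EVs"):
            window_difference(_particles([]), _particles([300.0]))

    def test_upper_windows_gain_under_scaling(self):
        """Scaling treated diameters x1.25 moves mass into the upper
        windows in nearly every random draw."""
        rng = np.random.default_rng(0)
        hits = 0
        n_seeds = 50
        for _ in range(n_seeds):
            base = np.exp(np.log(300) + 0.35 * rng.standard_normal(150))
            base = base[base > 200]
            treated = 1.25 * np.exp(np.log(300) + 0.35 * rng.standard_normal(150))
            treated = treated[treated > 200]
            out = window_difference(_particles(base), _particles(treated))
            upper = out.set_index("window").loc[["400-600", "600-800"], "difference"]
            if (upper > 0).any():
                hits += 1
        assert hits / n_seeds >= 0.9


class TestMannWhitney:
    def test_textbook_example(self):
        """x={1,2}, y={3,4}: U_x = 0 and the exact two-sided p is 2/6."""
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.u_statistic == 0.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="exact")
        assert res.p_value == pytest.approx(1.0)

    def test_u_complement_identity(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=9), rng.normal(size=12)
        ux = mann_whitney_u(x, y).u_statistic
        uy = mann_whitney_u(y, x).u_statistic
        assert ux + uy == pytest.approx(len(x) * len(y))

    @pytest.mark.parametrize("n,m", [(2, 3), (4, 4), (5, 3), (5, 5)])
    def test_exact_matches_enumeration_oracle(self, n, m):
        """Tie-free exact p equals the brute-force permutation oracle
        for every achievable U at these sample sizes."""
        rng = np.random.default_rng(n * 100 + m)
        for _ in range(20):
            x = rng.permutation(np.arange(n + m, dtype=float))[:n]
            y = np.setdiff1d(np.arange(n + m, dtype=float), x)
            res = mann_whitney_u(x, y)
            u_or, p_or = mwu_oracle_p(x, y)
            assert res.u_statistic == pytest.approx(u_or)
            assert res.p_value == pytest.approx(p_or, abs=1e-12)

    def test_forced_exact_with_ties_matches_oracle(self):
        cases = [
            ([1.0, 2.0, 2.0, 5.0], [2.0, 3.0, 3.0]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 2.0]),
            ([3.0, 3.0, 4.0, 4.0, 9.0], [3.0, 4.0, 4.0, 5.0]),
        ]
        for x, y in cases:
            res = mann_whitney_u(x, y, mode="exact")
            u_or, p_or = mwu_oracle_p(x, y)
            assert res.u_statistic == pytest.approx(u_or)
            assert res.p_value == pytest.approx(p_or, abs=1e-12)

    def test_normal_mode_agrees_with_scipy(self):
        """Tie-corrected normal approximation cross-checked against the
        reference implementation on larger tied samples."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = np.round(rng.normal(0, 2, size=60), 1)
            y = np.round(rng.normal(0.5, 2, size=75), 1)
            ours = mann_whitney_u(x, y, mode="normal")
            ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert ours.u_statistic == pytest.approx(
                len(x) * len(y) - ref.statistic
            ) or ours.u_statistic == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_mode_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(8)
        x = rng.permutation(np.arange(14.0))[:7]
        y = np.setdiff1d(np.arange(14.0), x)
        ours = mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(StatisticsError):
            mann_whitney_u([], [1.0])


class TestClassification:
    @pytest.mark.parametrize(
        "p_d,p_h,expected",
        [
            (0.031, 0.001, ("+", "+", "++")),
            (0.546, 0.0004, ("=", "+", "+")),
            (0.08, 0.002, ("=", "+", "+")),
            (0.795, 0.089, ("=", "=", "=")),
            (0.030, 0.803, ("+", "=", "+")),
        ],
    )
    def test_label_scheme(self, p_d, p_h, expected):
        label = classify_significance(p_d, p_h)
        assert (label.label_diameter, label.label_height, label.combined) == expected

    def test_invalid_p_rejected(self):
        with pytest.raises(StatisticsError):
            classify_significance(0.0, 0.5)
        with pytest.raises(StatisticsError):
            classify_significance(0.5, 1.5)

    @given(
        p_d=st.floats(1e-6, 1.0, exclude_max=False),
        p_h=st.floats(1e-6, 1.0, exclude_max=False),
    )
    def test_swapping_parameters_preserves_combined_count(self, p_d, p_h):
        a = classify_significance(p_d, p_h)
        b = classify_significance(p_h, p_d)
        assert a.combined == b.combined
        assert a.label_diameter == b.label_height
        assert a.label_height == b.label_diameter


class TestCompareConditions:
    def test_rerun_is_identical(self):
        rng = np.random.default_rng(3)
        control = {"L": _particles(np.exp(np.log(300) + 0.4 * rng.standard_normal(80)))}
        treated = {
            "L": _particles(
                1.3 * np.exp(np.log(300) + 0.4 * rng.standard_normal(80)),
                condition="treated",
            )
        }
        a = compare_conditions(control, treated)
        b = compare_conditions(control, treated)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_one_condition_ligand_skipped_with_warning(self, caplog):
        table = _particles([300.0] * 10)
        with caplog.at_level("WARNING"):
            cmp_ = compare_conditions({"A": table, "B": table}, {"A": table.copy()})
        assert list(cmp_.summary["ligand"]) == ["A"]
        assert "B" in caplog.text

    def test_shifted_ligand_labelled_significant(self):
        rng = np.random.default_rng(4)
        base = np.exp(np.log(320) + 0.35 * rng.standard_normal(200))
        shifted = 1.4 * np.exp(np.log(320) + 0.35 * rng.standard_normal(200))
        control = {"S": _particles(base), "N": _particles(base)}
        treated = {
            "S": _particles(shifted, condition="treated"),
            "N": _particles(base, condition="treated"),
        }
        summary = compare_conditions(control, treated).summary.set_index("ligand")
        assert summary.loc["S", "combined"] == "++"
        assert summary.loc["N", "combined"] == "="
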