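"""Reliability and agreement statistics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from footmorph import (
    BlandAltman,
    IntraclassCorrelation,
    ReliabilityAnalysis,
    RepeatedMeasures,
    bland_altman,
    icc_3_1,
    loa_percent,
    mdd,
    pearson_r,
    relative_mdd,
    sem,
    sem_ci,
    welch_t,
)


def anova_icc_oracle(m):
    """Brute-force two-way ANOVA decomposition for ICC(3,1)."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.mean()
    ss_rows = k * sum((m[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((m - grand) ** 2).sum()
    msr = ss_rows / (n - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


class TestICC:
    def test_identical_trials_give_perfect_icc(self):
        m = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        assert icc_3_1(m).estimate == pytest.approx(1.0)

    def test_constant_trial_offset_is_ignored(self):
        # consistency ICC removes the trial main effect
        c1 = np.array([1.0, 2.5, 4.0, 7.0])
        m = np.column_stack([c1, c1 + 0.5])
        assert icc_3_1(m).estimate == pytest.approx(1.0)

    def test_matches_hand_anova(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
        assert icc_3_1(m).estimate == pytest.approx(anova_icc_oracle(m), rel=1e-12)

    def test_matches_pingouin_icc3(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        m = rng.normal(10, 2, size=(20, 1)) + rng.normal(0, 0.5, size=(20, 3))
        df = pd.DataFrame(
            {
                "unit": np.repeat(np.arange(20), 3),
                "trial": np.tile(np.arange(3), 20),
                "y": m.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="unit", raters="trial", ratings="y")
        # ICC3 single-measure is labelled ICC3 or ICC(C,1) depending on version
        ref3 = ref[ref["Type"].isin(["ICC3", "ICC(C,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        res = icc_3_1(m)
        assert res.estimate == pytest.approx(ref3["ICC"], abs=1e-9)
        # pingouin rounds the interval to 2 decimals
        assert res.ci_low == pytest.approx(ref3[ci_col][0], abs=6e-3)
        assert res.ci_high == pytest.approx(ref3[ci_col][1], abs=6e-3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc_3_1(np.zeros((5, 2)))  # zero total variance
        with pytest.raises(ValueError):
            icc_3_1(np.array([[1.0, 2.0], [3.0, 4.0]]))  # n < 3
        with pytest.raises(ValueError):
            icc_3_1(np.array([[1.0], [2.0], [3.0]]))  # k < 2

    @given(
        scale=st.floats(0.1, 50),
        shift=st.floats(-100, 100),
        offset=st.floats(-5, 5),
    )
    @settings(deadline=None, max_examples=30)
    def test_affine_invariance(self, scale, shift, offset):
        rng = np.random.default_rng(99)
        m = rng.normal(10, 3, size=(12, 2)) + rng.normal(0, 1, size=(12, 2))
        base = icc_3_1(m).estimate
        m2 = scale * m + shift
        m2[:, 1] += offset  # constant added to one trial column
        assert icc_3_1(m2).estimate == pytest.approx(base, abs=1e-9)

    def test_estimator_attributes_and_ci_order(self, rng):
        m = rng.normal(5, 1, size=(15, 2))
        est = IntraclassCorrelation().fit(RepeatedMeasures(matrix=m))
        assert est.ci_low_ <= est.estimate_ <= est.ci_high_
        assert est.n_ == 15 and est.k_ == 2


class TestMeasurementErrorChain:
    @pytest.mark.parametrize("sd, icc, expected", [(1, 1, 0.0), (1, 0, 1.0), (2, 0.75, 1.0)])
    def test_sem_formula(self, sd, icc, expected):
        assert sem(sd, icc) == pytest.approx(expected)

    def test_sem_rejects_icc_above_one(self):
        with pytest.raises(ValueError):
            sem(1.0, 1.1)

    @pytest.mark.parametrize(
        "mean, sem_value, low, high",
        [(3.92, 0.078, 3.767, 4.073), (3.94, 0.074, 3.795, 4.085)],
    )
    def test_sem_ci_reported_values(self, mean, sem_value, low, high):
        lo, hi = sem_ci(mean, sem_value)
        assert round(lo, 3) == low and round(hi, 3) == high

    def test_sem_ci_degenerate(self):
        assert sem_ci(5.0, 0.0) == (5.0, 5.0)

    @pytest.mark.parametrize("sem_value, expected", [(0.078, 0.216), (0.089, 0.247), (0.0, 0.0)])
    def test_mdd_reported_values(self, sem_value, expected):
        assert round(mdd(sem_value), 3) == expected

    @pytest.mark.parametrize(
        "mdd_value, mean, expected", [(0.205, 3.94, 5.20), (0.208, 5.22, 3.98), (0.0, 7.0, 0.0)]
    )
    def test_relative_mdd_reported_values(self, mdd_value, mean, expected):
        assert round(relative_mdd(mdd_value, mean), 2) == expected

    def test_relative_mdd_needs_positive_mean(self):
        with pytest.raises(ValueError):
            relative_mdd(0.2, 0.0)

    @given(sd=st.floats(0, 10), icc=st.floats(-0.5, 1))
    @settings(deadline=None, max_examples=50)
    def test_chain_identity(self, sd, icc):
        assert mdd(sem(sd, icc)) == pytest.approx(sd * np.sqrt(1 - icc) * 1.96 * np.sqrt(2), rel=1e-12)


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    @given(a=st.floats(0.1, 10), b=st.floats(-10, 10))
    @settings(deadline=None, max_examples=30)
    def test_positive_affine_invariance(self, a, b):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert pearson_r(a * x + b, y) == pytest.approx(pearson_r(x, y), abs=1e-9)


class TestBlandAltman:
    def test_identical_methods(self):
        a = np.array([1.0, 2.0, 3.0])
        res = bland_altman(a, a)
        assert res.bias == 0 and res.loa_low == 0 and res.loa_high == 0 and res.loa_pct == 0

    def test_hand_computed(self):
        res = bland_altman([1.0, 2.0, 3.0], [0.0, 2.0, 4.0])
        assert res.bias == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(-1.96)
        assert res.loa_high == pytest.approx(1.96)

    def test_antisymmetry_under_order_swap(self, rng):
        a, b = rng.normal(10, 2, 30), rng.normal(10, 2, 30)
        ab, ba = bland_altman(a, b), bland_altman(b, a)
        assert ab.bias == pytest.approx(-ba.bias)
        assert ab.loa_low == pytest.approx(-ba.loa_high)
        assert ab.loa_pct == pytest.approx(ba.loa_pct)

    def test_reference_means_override(self):
        res = bland_altman([1.0, 2.0, 3.0], [0.0, 2.0, 4.0], mean_a=3.92, mean_b=3.94)
        assert res.reference_mean == pytest.approx(3.93)
        assert res.loa_pct == pytest.approx(100 * 1.96 / 3.93)

    def test_loa_percent_reported_fascia_row(self):
        # half-width of (-0.38, 0.34) against pooled method means 3.92/3.94
        assert round(loa_percent(-0.38, 0.34, (3.92 + 3.94) / 2), 1) == 9.2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2, 3], [1, 2])

    def test_loa_coverage_near_95_percent(self, rng):
        truth = rng.normal(14, 4.5, 10000)
        a = truth + rng.normal(0, 0.3, truth.size)
        b = truth + rng.normal(0, 0.3, truth.size)
        est = BlandAltman().fit(a, b)
        inside = np.mean((est.diffs_ >= est.loa_low_) & (est.diffs_ <= est.loa_high_))
        assert inside == pytest.approx(0.95, abs=0.01)


class TestReliabilityAnalysis:
    def test_row_bundle_consistency(self, rng):
        m = rng.normal(14, 4.5, size=(40, 1)) + rng.normal(0, 0.45, size=(40, 2))
        rel = ReliabilityAnalysis().fit(m)
        row = rel.row_()
        assert row.mdd == pytest.approx(row.sem * 1.96 * np.sqrt(2), rel=1e-12)
        assert row.mdd_pct == pytest.approx(100 * row.mdd / row.mean, rel=1e-12)
        assert row.sem_ci == (pytest.approx(row.mean - 1.96 * row.sem), pytest.approx(row.mean + 1.96 * row.sem))

    def test_sd_modes_differ(self, rng):
        m = rng.normal(10, 2, size=(30, 1)) + rng.normal(0, 1.0, size=(30, 2))
        pooled = ReliabilityAnalysis(sd_mode="pooled").fit(m).sd_
        trial = ReliabilityAnalysis(sd_mode="trial_means").fit(m).sd_
        assert pooled > trial  # trial means average away within-trial noise


class TestWelch:
    def test_identical_groups_null(self):
        g = [1.0, 2.0, 3.0, 4.0]
        stat, p = welch_t(g, g)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_sign_flips_with_group_order(self, rng):
        g1, g2 = rng.normal(5, 1, 18), rng.normal(4, 1, 38)
        s12, p12 = welch_t(g1, g2)
        s21, p21 = welch_t(g2, g1)
        assert s12 == pytest.approx(-s21)
        assert p12 == pytest.approx(p21)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
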