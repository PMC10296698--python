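"""Domain scoring: normality check, Box–Cox, standardization, composites."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cogaging.errors import InsufficientDataError, ValidationError
from cogaging.scoring import (
    DEFAULT_BATTERY,
    BoxCoxParams,
    DomainScorer,
    apply_boxcox,
    assess_normality,
    domain_scores,
    fit_boxcox,
    standardize,
)
from cogaging.scoring import TestSchema as BatteryTest


class TestAssessNormality:
    def test_symmetric_sample_is_normal(self, rng):
        half = rng.normal(3.0, 1.0, size=100)
        mirrored = np.concatenate([half, 2 * half.mean() - half])
        assert assess_normality(mirrored) == "normal"

    def test_exponential_sample_is_non_normal(self, rng):
        assert assess_normality(rng.exponential(1.0, size=500)) == "non_normal"

    def test_too_few_values_raises(self):
        with pytest.raises(InsufficientDataError):
            assess_normality(np.arange(10))

    def test_constant_sample_raises(self):
        with pytest.raises(InsufficientDataError):
            assess_normality(np.full(30, 7.0))


class TestBoxCox:
    def test_lognormal_recovers_log_transform(self, rng):
        x = rng.lognormal(mean=1.0, sigma=0.6, size=2000)
        params = fit_boxcox(x)
        assert params.shift == 0.0
        assert -0.15 <= params.lmbda <= 0.15

    def test_agrees_with_scipy_optimizer(self, rng):
        x = rng.gamma(2.0, 3.0, size=1500)
        params = fit_boxcox(x)
        _, lam_scipy = stats.boxcox(x)
        assert abs(params.lmbda - lam_scipy) <= 0.02

    def test_shift_applied_when_zero_present(self, rng):
        x = np.concatenate([[0.0], rng.exponential(2.0, size=200)])
        params = fit_boxcox(x)
        assert params.shift == pytest.approx(1.0 - x.min())
        assert (x + params.shift).min() == pytest.approx(1.0)

    def test_transform_reduces_skewness(self, rng):
        for sample in (rng.lognormal(0, 0.8, 800), rng.exponential(1.0, 800)):
            params = fit_boxcox(sample)
            before = abs(stats.skew(sample))
            after = abs(stats.skew(apply_boxcox(sample, params)))
            assert after <= before

    def test_already_normal_sample_does_not_increase_skewness(self, rng):
        x = rng.normal(50.0, 5.0, size=1000)
        params = fit_boxcox(x)
        assert abs(stats.skew(apply_boxcox(x, params))) <= abs(stats.skew(x)) + 1e-9

    def test_zero_variance_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_boxcox(np.full(50, 3.0))

    def test_log_branch_at_lambda_zero(self):
        x = np.array([1.0, np.e, np.e**2])
        out = apply_boxcox(x, BoxCoxParams(lmbda=0.0))
        np.testing.assert_allclose(out, [0.0, 1.0, 2.0])


def _reference_fit(df, **kw):
    return DomainScorer(**kw).fit(df)


class TestStandardize:
    def test_reference_idempotence(self, small_cohort):
        v = small_cohort.visits
        baseline_controls = v[(v["group"] == "control") & (v["month"] == 0)]
        scorer = _reference_fit(baseline_controls)
        z = scorer.transform(baseline_controls)
        assert z.mean().abs().max() < 1e-9
        assert (z.std(ddof=1) - 1).abs().max() < 1e-9

    def test_value_at_reference_mean_is_zero(self, small_cohort):
        v = small_cohort.visits
        bc = v[(v["group"] == "control") & (v["month"] == 0)]
        scorer = _reference_fit(bc, use_boxcox=False)
        ref = scorer.reference_["digit_symbol"]
        row = bc.iloc[[0]].copy()
        row["digit_symbol"] = ref.mean
        assert scorer.transform(row)["digit_symbol"].iloc[0] == pytest.approx(0.0)

    def test_higher_worse_direction_flip(self, small_cohort):
        """A timed score one reference SD above the mean lands at z = -1."""
        v = small_cohort.visits
        bc = v[(v["group"] == "control") & (v["month"] == 0)]
        scorer = _reference_fit(bc, use_boxcox=False)
        ref = scorer.reference_["trail_making_b"]
        row = bc.iloc[[0]].copy()
        row["trail_making_b"] = ref.mean + ref.sd
        assert scorer.transform(row)["trail_making_b"].iloc[0] == pytest.approx(-1.0)

    def test_direction_is_strictly_monotone(self, small_cohort):
        v = small_cohort.visits
        bc = v[(v["group"] == "control") & (v["month"] == 0)]
        scorer = _reference_fit(bc)
        rows = bc.iloc[[0, 0]].copy()
        rows.iloc[1, rows.columns.get_loc("trail_making_a")] += 10.0
        z = scorer.transform(rows)["trail_making_a"]
        assert z.iloc[1] < z.iloc[0]

    def test_unknown_test_raises(self, small_cohort):
        v = small_cohort.visits
        bc = v[(v["group"] == "control") & (v["month"] == 0)]
        scorer = _reference_fit(bc)
        with pytest.raises(ValidationError, match="absent from"):
            standardize(bc, {"digit_symbol": scorer.reference_["digit_symbol"]})

    def test_affine_invariance_without_transform(self, small_cohort):
        """With the power transform disabled, a positive affine rescaling of
        a raw test changes neither its z-scores nor the composites."""
        v = small_cohort.visits
        bc = v[(v["group"] == "control") & (v["month"] == 0)]
        z0 = _reference_fit(bc, use_boxcox=False).transform(v)
        v2, bc2 = v.copy(), bc.copy()
        for df in (v2, bc2):
            df["digit_symbol"] = 3.0 * df["digit_symbol"] + 11.0
        z1 = _reference_fit(bc2, use_boxcox=False).transform(v2)
        pd.testing.assert_frame_equal(z0, z1, atol=1e-9, rtol=0)


class TestDomainScores:
    three = (
        BatteryTest("a", "APE"), BatteryTest("b", "APE"), BatteryTest("c", "APE"),
    )

    def test_mean_of_members(self):
        z = pd.DataFrame({"a": [0.5, 1.0], "b": [0.5, -1.0], "c": [0.5, 0.0]})
        out = domain_scores(z, self.three)
        assert out["APE"].tolist() == [0.5, 0.0]
        assert out["n_tests_APE"].tolist() == [3, 3]

    def test_half_rule_marks_missing(self):
        ape_tests = [t.name for t in DEFAULT_BATTERY if t.domain == "APE"]
        z = pd.DataFrame({t: [0.2] for t in ape_tests[:3]})
        for t in ape_tests[3:]:
            z[t] = np.nan
        out = domain_scores(z, DEFAULT_BATTERY)
        assert np.isnan(out["APE"].iloc[0])  # 3 of 7 present < ceil(3.5)
        z[ape_tests[3]] = 0.2
        out = domain_scores(z, DEFAULT_BATTERY)
        assert out["APE"].iloc[0] == pytest.approx(0.2)  # 4 of 7 suffices

    def test_duplicate_test_rejected(self):
        with pytest.raises(ValidationError, match="twice"):
            domain_scores(pd.DataFrame({"a": [1.0]}),
                          (BatteryTest("a", "APE"), BatteryTest("a", "LM")))


def test_score_panel_carries_ids(small_cohort):
    v = small_cohort.visits
    bc = v[(v["group"] == "control") & (v["month"] == 0)]
    panel = _reference_fit(bc).score_panel(v)
    assert list(panel.columns[:2]) == ["participant_id", "month"]
    assert len(panel) == len(v)
    assert panel["APE"].notna().all()  # complete synthetic data
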