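"""Design construction, HDI, split R-hat and the Gibbs-fitted growth model."""

import numpy as np
import pandas as pd
import pytest

from cogaging.errors import InsufficientDataError, ValidationError
from cogaging.model import (
    FIXED_NAMES,
    GrowthCurveModel,
    build_design,
    hdi,
    rhat,
)
from cogaging.simulate import CohortConfig, generate_cohort


def _panel(n=40, ages=None, months=(0.0, 8.0, 16.0, 24.0), seed=0):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(60, 89, n) if ages is None else np.full(n, ages)
    rows = []
    for k in range(n):
        for m in months:
            rows.append(
                {"participant_id": f"P{k:03d}",
                 "group": "survivor" if k % 2 else "control",
                 "age_enroll": ages[k], "month": m,
                 "y": rng.normal()}
            )
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_centering_at_sample_mean(self):
        df = _panel(ages=72.5)
        d = build_design(df, "y")
        assert d.center == 72.5
        np.testing.assert_allclose(d.centered_age, 0.0)
        np.testing.assert_allclose(d.X[:, [1, 2, 4, 5]], 0.0)  # age columns zero

    def test_explicit_center(self):
        df = _panel(ages=65.0)
        d = build_design(df, "y", center=72.5)
        np.testing.assert_allclose(d.centered_age, -7.5)

    def test_quartile_boundaries(self):
        df = pd.concat([_panel(n=2, ages=a, seed=k)
                        for k, a in enumerate([68, 69, 77])])
        df["participant_id"] = df["participant_id"] + df["age_enroll"].astype(str)
        d = build_design(df, "y", center=72.5)
        by_age = dict(zip(d.centered_age + 72.5, d.quartile))
        assert by_age[68.0] == 1 and by_age[69.0] == 2 and by_age[77.0] == 4

    def test_missing_age_or_group_goes_to_rejects(self):
        df = _panel(n=10)
        df.loc[df["participant_id"] == "P000", "age_enroll"] = np.nan
        d = build_design(df, "y")
        assert "P000" in d.rejects["participant_id"].values
        assert "P000" not in d.participant_ids

    def test_missing_columns_raise(self):
        with pytest.raises(ValidationError, match="missing columns"):
            build_design(pd.DataFrame({"participant_id": []}), "y")


class TestHdi:
    def test_uniform_grid_lowest_start_tie_break(self):
        lo, hi = hdi(np.arange(1.0, 101.0), 0.95)
        assert (lo, hi) == (1.0, 95.0)

    def test_all_draws_equal_gives_zero_width(self):
        assert hdi(np.full(500, 3.3)) == (3.3, 3.3)

    def test_symmetric_sample_close_to_equal_tailed(self, rng):
        x = rng.normal(0.0, 1.0, size=100_000)
        lo, hi = hdi(x, 0.95)
        qlo, qhi = np.quantile(x, [0.025, 0.975])
        assert abs(lo - qlo) < 0.05 and abs(hi - qhi) < 0.05

    def test_matches_arviz(self, rng):
        az = pytest.importorskip("arviz")
        x = rng.gamma(2.0, 1.0, size=50_000)
        lo, hi = hdi(x, 0.95)
        ref = az.hdi(x, hdi_prob=0.95)
        assert lo == pytest.approx(ref[0], abs=0.02)
        assert hi == pytest.approx(ref[1], abs=0.02)

    def test_bad_prob_raises(self):
        with pytest.raises(ValidationError):
            hdi(np.arange(200.0), prob=1.2)

    def test_too_few_draws_raises(self):
        with pytest.raises(InsufficientDataError):
            hdi(np.arange(10.0))


class TestRhat:
    def test_identical_chains_near_one(self, rng):
        chain = rng.normal(size=1000)
        assert rhat(np.stack([chain, chain])) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.normal(-10, 1, 1000), rng.normal(10, 1, 1000)])
        assert rhat(chains) > 3.0

    def test_formula_against_direct_evaluation(self, rng):
        chains = rng.normal(size=(4, 500))
        halves = chains.reshape(8, 250)
        W = halves.var(axis=1, ddof=1).mean()
        B = 250 * halves.mean(axis=1).var(ddof=1)
        expect = np.sqrt((249 / 250 * W + B / 250) / W)
        assert rhat(chains) == pytest.approx(expect, rel=1e-12)

    def test_single_chain_raises(self):
        with pytest.raises(ValidationError):
            rhat(np.arange(100.0)[None, :])

    def test_short_chains_raise(self):
        with pytest.raises(InsufficientDataError):
            rhat(np.zeros((2, 3)))


class TestGrowthCurveModel:
    def test_null_data_posteriors_center_on_zero(self):
        df = _panel(n=30, seed=1)
        df["y"] = 0.0
        est = GrowthCurveModel(outcome="y", chains=2, iterations=600, warmup=200,
                               random_state=0)
        with pytest.warns(UserWarning):
            est.fit(df)
        for name in FIXED_NAMES:
            row = est.summary_.loc[name]
            assert row["hdi_lo"] - 1e-9 <= 0.0 <= row["hdi_hi"] + 1e-9
            assert abs(row["mean"]) < 0.05

    def test_single_visit_data_flags_slope_block(self):
        df = _panel(n=30, months=(0.0,), seed=2)
        est = GrowthCurveModel(outcome="y", chains=2, iterations=400, warmup=100,
                               random_state=0)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            est.fit(df)
        assert any("single-visit" in w for w in est.warnings_)

    def test_degenerate_age_column_still_fits(self):
        df = _panel(n=30, ages=72.5, seed=3)
        est = GrowthCurveModel(outcome="y", chains=2, iterations=400, warmup=100,
                               random_state=0)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            est.fit(df)
        assert any("degenerate" in w for w in est.warnings_)
        assert np.isfinite(est.summary_["mean"]).all()

    def test_posterior_variance_parameters_respect_support(self, small_cohort):
        import warnings as _w
        est = GrowthCurveModel(outcome="APE", chains=2, iterations=800,
                               warmup=200, random_state=5)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            est.fit(small_cohort.domain_truth)
        for name in ("sigma_alpha", "sigma_beta", "sigma_eps"):
            assert (est.posterior_.draws[name] > 0).all()
        rho_draws = est.posterior_.draws["rho"]
        assert (rho_draws > -1).all() and (rho_draws < 1).all()
        lo = est.summary_["hdi_lo"]
        hi = est.summary_["hdi_hi"]
        assert (lo <= est.summary_["mean"]).all()
        assert (est.summary_["mean"] <= hi).all()

    def test_prior_dominated_fit_returns_prior(self):
        """With one participant, one visit and an enormous residual prior,
        fixed-effect posteriors stay at their Normal(0, sd) priors."""
        df = pd.DataFrame(
            [{"participant_id": "P0", "group": "control",
              "age_enroll": 72.5, "month": 0.0, "y": 0.0}]
        )
        prior_sd = np.full(14, 1.0)
        est = GrowthCurveModel(
            outcome="y", chains=2, iterations=3000, warmup=500, random_state=0,
            priors={"gamma_sd": prior_sd, "eps_a0": 50.0, "eps_b0": 50.0 * 1e4},
        )
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            est.fit(df)
        g = est.posterior_.flat("g03")
        assert abs(g.mean()) < 0.15
        assert 0.75 < g.std() < 1.25

    def test_group_label_swap_negates_survivor_contrasts(self):
        cfg = CohortConfig(n_survivors=120, n_controls=80, seed=21,
                           dropout_hazard=0.0)
        cohort = generate_cohort(cfg)
        panel = cohort.domain_truth
        swapped = panel.copy()
        swapped["group"] = panel["group"].map(
            {"survivor": "control", "control": "survivor"}
        )
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            a = GrowthCurveModel(outcome="APE", preset="test", center=72.5,
                                 random_state=1).fit(panel).summary_
            b = GrowthCurveModel(outcome="APE", preset="test", center=72.5,
                                 random_state=1).fit(swapped).summary_
        for name in ("g03", "g04", "g11"):
            assert a.loc[name, "mean"] == pytest.approx(-b.loc[name, "mean"], abs=0.05)

    def test_predict_uses_fixed_effects(self, small_cohort):
        import warnings as _w
        est = GrowthCurveModel(outcome="APE", chains=2, iterations=800,
                               warmup=200, random_state=3)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            est.fit(small_cohort.domain_truth)
        pred = est.predict(small_cohort.domain_truth)
        assert pred.shape[0] == len(small_cohort.domain_truth)
        assert np.isfinite(pred).all()

    def test_sklearn_param_interface(self):
        est = GrowthCurveModel(outcome="LM", chains=3)
        assert est.get_params()["outcome"] == "LM"
        est.set_params(chains=5)
        assert est.chains == 5

    def test_fewer_than_two_chains_rejected(self):
        with pytest.raises(ValidationError, match="chains"):
            GrowthCurveModel(outcome="y", chains=1).fit(_panel(n=5))
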