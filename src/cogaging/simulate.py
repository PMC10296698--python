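"""Synthetic two-cohort longitudinal study generator.

Emulates the statistical structure of an observational aging study with a
cancer-survivor cohort (~328) and a non-cancer control cohort (~158), ages
60–89 (mean ~72.5), assessed at months 0, 8, 16 and 24 on a battery of
neuropsychological tests and a 44-item ordinal frailty battery.

The generating model mirrors the analysis model exactly so that recovery
of the generating parameters is a meaningful end-to-end check:

* person-level intercepts follow a group-specific quadratic in centered
  enrollment age (gamma_00..gamma_05),
* person-level slopes over months follow group x baseline-age-quartile
  means (gamma_10, gamma_11, gamma_12.k, gamma_13.k),
* person-level deviations (u_i, v_i) are bivariate normal with SDs
  (sigma_alpha, sigma_beta) and correlation rho,
* visit-level residuals are Normal(0, sigma_eps).

Raw test scores are per-test affine maps of the domain score plus noise
that can be skewed through a sinh-arcsinh tilt (skew = 0 reduces exactly
to Gaussian noise), so the downstream Box–Cox step has realistic work to
do.  Frailty indicators are independent ordinal draws whose adverse-code
probabilities rise with age and are elevated in survivors, more so at
younger ages.  Dropout is monotone: once a participant misses a visit,
all later visits are missing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .errors import ConfigError
from .scoring import DEFAULT_BATTERY, TestSchema

GAMMA_NAMES = (
    "g00", "g01", "g02", "g03", "g04", "g05",
    "g10", "g11", "g12_2", "g12_3", "g12_4", "g13_2", "g13_3", "g13_4",
)

DEFAULT_QUARTILE_BINS = ((60, 68), (69, 72), (73, 76), (77, 89))


@dataclass(frozen=True)
class GammaVector:
    """Fixed-effect vector of the varying-intercepts/varying-slopes model.

    Intercept block (per-year scale, age centered): g00 overall, g01
    linear age, g02 quadratic age, g03/g04/g05 the survivor differences.
    Slope block (per-month scale): g10 overall months slope, g11 survivor
    difference, g12_k quartile-k offsets, g13_k survivor x quartile-k
    offsets (k = 2..4, youngest quartile is the reference).
    """

    g00: float = 0.0
    g01: float = 0.0
    g02: float = 0.0
    g03: float = 0.0
    g04: float = 0.0
    g05: float = 0.0
    g10: float = 0.0
    g11: float = 0.0
    g12_2: float = 0.0
    g12_3: float = 0.0
    g12_4: float = 0.0
    g13_2: float = 0.0
    g13_3: float = 0.0
    g13_4: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in GAMMA_NAMES])

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in GAMMA_NAMES}


# Defaults reproduce the structure of a published survivor/control cohort
# analysis; the APE quadratic survivor difference uses the value consistent
# with its interval (-0.001).
DEFAULT_GAMMAS: dict[str, GammaVector] = {
    "APE": GammaVector(
        g00=0.013, g01=-0.047, g02=0.00001, g03=-0.130, g04=0.016, g05=-0.001,
        g10=0.004, g11=0.0002, g12_2=0.001, g12_3=-0.002, g12_4=-0.008,
        g13_2=-0.001, g13_3=0.0004, g13_4=0.005,
    ),
    "LM": GammaVector(
        g00=0.048, g01=-0.048, g02=-0.0006, g03=-0.205, g04=0.012, g05=0.0004,
        g10=0.019, g11=-0.0029, g12_2=0.0006, g12_3=-0.007, g12_4=-0.007,
        g13_2=0.0005, g13_3=0.0073, g13_4=0.0053,
    ),
}

DEFAULT_SIGMA_ALPHA = {"APE": 0.60, "LM": 0.64}
DEFAULT_SIGMA_BETA = {"APE": 0.004, "LM": 0.005}
DEFAULT_RHO = {"APE": 0.16, "LM": 0.27}
DEFAULT_SIGMA_EPS = {"APE": 0.194, "LM": 0.361}


@dataclass(frozen=True)
class TestGenSchema:
    """How one raw test is synthesized from its domain score.

    raw = offset + loading * (domain score) + noise_sd * sinh(asinh(Z) + skew)

    with the loading negated for ``higher_worse`` tests.  ``skew`` > 0
    yields right-skewed noise; 0 is exactly Gaussian.
    """

    name: str
    domain: str
    direction: str
    offset: float
    loading: float
    noise_sd: float
    skew: float = 0.0


def default_test_gen_schema() -> tuple[TestGenSchema, ...]:
    """Plausible raw-score scales for the default battery.

    Timed tests get right-skewed noise (completion times pile up near a
    floor with a long upper tail); score-count tests stay near Gaussian.
    """
    scales = {
        "digit_symbol": (45.0, 10.0, 6.0, 0.0),
        "trail_making_a": (38.0, 9.0, 8.0, 0.9),
        "trail_making_b": (95.0, 25.0, 22.0, 1.1),
        "dkefs_color_word": (55.0, 10.0, 9.0, 0.8),
        "nab_digits_forward": (8.0, 1.5, 1.5, 0.0),
        "nab_digits_backward": (6.5, 1.5, 1.4, 0.0),
        "nab_driving_scenes": (45.0, 8.0, 6.0, 0.0),
        "nab_ll_trial1": (5.5, 1.3, 1.2, 0.0),
        "nab_ll_semantic_clustering": (4.0, 1.2, 1.3, 0.4),
        "nab_ll_list_a_immediate": (20.0, 4.0, 3.0, 0.0),
        "nab_ll_list_a_delayed": (7.0, 2.0, 1.8, 0.0),
        "nab_ll_long_delay": (7.0, 2.2, 1.9, 0.0),
        "nab_ll_list_b_immediate": (5.0, 1.5, 1.4, 0.0),
        "nab_ll_recognition": (0.9, 0.05, 0.05, -0.6),
        "logical_memory_1": (13.0, 3.5, 3.0, 0.0),
        "logical_memory_2": (11.0, 3.5, 3.2, 0.3),
    }
    out = []
    for t in DEFAULT_BATTERY:
        offset, loading, noise, skew = scales[t.name]
        out.append(TestGenSchema(t.name, t.domain, t.direction, offset, loading, noise, skew))
    return tuple(out)


@dataclass(frozen=True)
class IndicatorGenSchema:
    """Ordinal-indicator generator: cumulative-logit probabilities.

    At the reference (control, age = age_mean, month 0) the indicator shows
    code >= 1 with probability ``p_any`` and code 2 with probability
    ``p_severe``.  The linear predictor is shifted by ``age_slope`` per
    year of (current) age, by a survivor offset that declines linearly
    with age (so cohort gaps are widest in the younger range), and by
    ``month_slope`` per study month.
    """

    name: str
    p_any: float
    p_severe: float
    age_slope: float = 0.045
    survivor_lor_at_60: float = 0.9
    survivor_lor_age_slope: float = -0.05
    month_slope: float = 0.008


def default_indicator_schema(n: int = 44) -> tuple[IndicatorGenSchema, ...]:
    """A fixed, deterministic spread of prevalences for ``n`` indicators."""
    out = []
    for j in range(n):
        p_any = 0.10 + 0.22 * ((j * 7) % 11) / 10.0
        p_severe = 0.02 + 0.06 * ((j * 3) % 7) / 6.0
        out.append(IndicatorGenSchema(name=f"i{j + 1:02d}", p_any=p_any, p_severe=p_severe))
    return tuple(out)


def _as_domain_map(value, domains: Sequence[str], name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {d: float(value[d]) for d in domains}
    return {d: float(value) for d in domains}


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    Scalar variance parameters are broadcast to every domain; mappings
    keyed by domain name ("APE", "LM") set them per domain.
    """

    n_survivors: int = 328
    n_controls: int = 158
    age_range: tuple[float, float] = (60.0, 89.0)
    age_mean: float = 72.5
    age_sd: float = 5.8
    visit_months: tuple[float, ...] = (0.0, 8.0, 16.0, 24.0)
    true_gammas: Mapping[str, GammaVector] = field(
        default_factory=lambda: dict(DEFAULT_GAMMAS)
    )
    sigma_alpha: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_SIGMA_ALPHA)
    )
    sigma_beta: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_SIGMA_BETA)
    )
    rho: Mapping[str, float] | float = field(default_factory=lambda: dict(DEFAULT_RHO))
    sigma_eps: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_SIGMA_EPS)
    )
    quartile_bins: tuple[tuple[float, float], ...] = DEFAULT_QUARTILE_BINS
    test_schema: tuple[TestGenSchema, ...] = field(default_factory=default_test_gen_schema)
    indicator_schema: tuple[IndicatorGenSchema, ...] = field(
        default_factory=default_indicator_schema
    )
    missing_rate: float = 0.02
    dropout_hazard: float = 0.08
    seed: int = 0

    @property
    def domains(self) -> tuple[str, ...]:
        if isinstance(self.true_gammas, GammaVector):
            return ("APE",)
        return tuple(self.true_gammas.keys())

    def gammas(self, domain: str) -> GammaVector:
        if isinstance(self.true_gammas, GammaVector):
            return self.true_gammas
        return self.true_gammas[domain]

    def validate(self) -> None:
        if self.n_survivors < 0:
            raise ConfigError("n_survivors must be >= 0")
        if self.n_controls < 0:
            raise ConfigError("n_controls must be >= 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError("age_range must satisfy lo < hi")
        if not lo <= self.age_mean <= hi:
            raise ConfigError("age_mean must lie within age_range")
        if self.age_sd <= 0:
            raise ConfigError("age_sd must be > 0")
        months = tuple(self.visit_months)
        if not months or months[0] != 0:
            raise ConfigError("visit_months must start at 0")
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ConfigError("visit_months must be strictly increasing")
        doms = self.domains
        for name, val in (
            ("sigma_alpha", self.sigma_alpha),
            ("sigma_beta", self.sigma_beta),
            ("sigma_eps", self.sigma_eps),
        ):
            m = _as_domain_map(val, doms, name)
            if any(v <= 0 for v in m.values()):
                raise ConfigError(f"{name} must be > 0")
        rho = _as_domain_map(self.rho, doms, "rho")
        if any(not -1 < v < 1 for v in rho.values()):
            raise ConfigError("rho must lie in (-1, 1)")
        if not 0 <= self.missing_rate <= 1:
            raise ConfigError("missing_rate must lie in [0, 1]")
        if not 0 <= self.dropout_hazard <= 1:
            raise ConfigError("dropout_hazard must lie in [0, 1]")
        if len(self.quartile_bins) != 4:
            raise ConfigError("quartile_bins must list 4 bins")
        for s in self.indicator_schema:
            if not (0 <= s.p_severe <= s.p_any <= 1):
                raise ConfigError(f"indicator_schema[{s.name}]: invalid probabilities")


@dataclass(frozen=True)
class VisitRecord:
    """One participant-visit: raw test scores plus frailty indicators."""

    participant_id: str
    group: str
    age_enroll: float
    month: float
    test_scores: dict[str, float]
    indicators: tuple[float, ...]


@dataclass
class Cohort:
    """Generated study data plus the ground truth that produced it."""

    visits: pd.DataFrame  # participant_id, group, age_enroll, month, tests...
    indicators: pd.DataFrame  # participant_id, month, i01..iNN
    domain_truth: pd.DataFrame  # participant_id, group, age_enroll, month, <domain obs>
    truth: dict  # generating parameters and latent effects summary
    config: CohortConfig

    def records(self) -> Iterator[VisitRecord]:
        test_cols = [s.name for s in self.config.test_schema]
        ind_cols = [s.name for s in self.config.indicator_schema]
        ind = self.indicators.set_index(["participant_id", "month"])
        for _, row in self.visits.iterrows():
            key = (row["participant_id"], row["month"])
            yield VisitRecord(
                participant_id=row["participant_id"],
                group=row["group"],
                age_enroll=float(row["age_enroll"]),
                month=float(row["month"]),
                test_scores={c: float(row[c]) for c in test_cols},
                indicators=tuple(float(v) for v in ind.loc[key, ind_cols]),
            )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write visit/indicator CSVs and a ground-truth JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "visits": outdir / "visits.csv",
            "indicators": outdir / "indicators.csv",
            "domain_truth": outdir / "domain_truth.csv",
            "truth": outdir / "truth.json",
        }
        self.visits.to_csv(paths["visits"], index=False)
        self.indicators.to_csv(paths["indicators"], index=False)
        self.domain_truth.to_csv(paths["domain_truth"], index=False)
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        return paths


def assign_quartile(age, bins=DEFAULT_QUARTILE_BINS) -> np.ndarray:
    """Baseline-age quartile index 1..4; edges follow the configured bins."""
    age = np.atleast_1d(np.asarray(age, dtype=float))
    edges = [b[1] for b in bins[:-1]]
    q = np.digitize(age, edges, right=True) + 1
    return q


def level2_intercept(g: GammaVector, c: np.ndarray, survivor: np.ndarray) -> np.ndarray:
    """Expected person intercept: quadratic in centered age, by group."""
    base = g.g00 + g.g01 * c + g.g02 * c**2
    diff = g.g03 + g.g04 * c + g.g05 * c**2
    return base + survivor * diff


def level2_slope(g: GammaVector, quartile: np.ndarray, survivor: np.ndarray) -> np.ndarray:
    """Expected per-month slope: group x baseline-age-quartile means."""
    g12 = {2: g.g12_2, 3: g.g12_3, 4: g.g12_4}
    g13 = {2: g.g13_2, 3: g.g13_3, 4: g.g13_4}
    out = np.full(quartile.shape, g.g10, dtype=float) + g.g11 * survivor
    for k in (2, 3, 4):
        mask = quartile == k
        out[mask] += g12[k] + g13[k] * survivor[mask]
    return out


def true_gap_curve(
    config: CohortConfig, ages: np.ndarray, domain: str = "APE"
) -> np.ndarray:
    """Generating survivor-minus-control difference over an age grid.

    Evaluates g03 + g04*(a - center) + g05*(a - center)^2 with the
    configured gammas; the oracle for the post-hoc gap analysis.
    """
    ages = np.asarray(ages, dtype=float)
    lo, hi = config.age_range
    if ages.min() < lo or ages.max() > hi:
        raise ConfigError("ages must lie within config.age_range")
    g = config.gammas(domain)
    c = ages - config.age_mean
    return g.g03 + g.g04 * c + g.g05 * c**2


def _skewed_noise(rng: np.random.Generator, size, sd: float, skew: float) -> np.ndarray:
    """sinh-arcsinh tilt of standard normal noise; skew = 0 is Gaussian."""
    z = rng.standard_normal(size)
    if skew == 0.0:
        return sd * z
    return sd * np.sinh(np.arcsinh(z) + skew)


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Draw one synthetic cohort.

    Deterministic given ``(config, seed)``; ``seed`` overrides
    ``config.seed`` when given.  All randomness flows from one root
    :class:`numpy.random.SeedSequence`.
    """
    config = config if config is not None else CohortConfig()
    config.validate()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    rng_people, rng_effects, rng_tests, rng_ind, rng_drop = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    n = config.n_survivors + config.n_controls
    months = np.asarray(config.visit_months, dtype=float)
    n_visits = months.size
    domains = config.domains

    # --- participants ------------------------------------------------
    lo, hi = config.age_range
    a_std = (lo - config.age_mean) / config.age_sd
    b_std = (hi - config.age_mean) / config.age_sd
    ages = stats.truncnorm.rvs(
        a_std, b_std, loc=config.age_mean, scale=config.age_sd, size=n,
        random_state=rng_people,
    )
    survivor = np.concatenate(
        [np.ones(config.n_survivors), np.zeros(config.n_controls)]
    )
    pid = np.array([f"P{k + 1:04d}" for k in range(n)])
    group = np.where(survivor == 1, "survivor", "control")
    c = ages - config.age_mean
    quart = assign_quartile(ages, config.quartile_bins)

    # --- dropout (shared across domains/instruments) ------------------
    # baseline always observed; thereafter geometric survival
    if n_visits > 1:
        cont = rng_drop.random((n, n_visits - 1)) >= config.dropout_hazard
        observed = np.column_stack([np.ones(n, bool), np.cumprod(cont, axis=1).astype(bool)])
    else:
        observed = np.ones((n, 1), bool)

    sa = _as_domain_map(config.sigma_alpha, domains, "sigma_alpha")
    sb = _as_domain_map(config.sigma_beta, domains, "sigma_beta")
    rho = _as_domain_map(config.rho, domains, "rho")
    se = _as_domain_map(config.sigma_eps, domains, "sigma_eps")

    # --- domain-level observations ------------------------------------
    dom_obs: dict[str, np.ndarray] = {}
    latent: dict[str, dict[str, list[float]]] = {}
    for d in domains:
        g = config.gammas(d)
        cov = np.array(
            [[sa[d] ** 2, rho[d] * sa[d] * sb[d]],
             [rho[d] * sa[d] * sb[d], sb[d] ** 2]]
        )
        uv = rng_effects.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
        alpha = level2_intercept(g, c, survivor) + uv[:, 0]
        beta = level2_slope(g, quart, survivor) + uv[:, 1]
        eps = rng_effects.standard_normal((n, n_visits)) * se[d]
        dom_obs[d] = alpha[:, None] + beta[:, None] * months[None, :] + eps
        latent[d] = {"alpha": alpha.tolist(), "beta": beta.tolist()}

    # --- raw test scores ----------------------------------------------
    test_cols: dict[str, np.ndarray] = {}
    for s in config.test_schema:
        if s.domain not in dom_obs:
            continue
        sign = -1.0 if s.direction == "higher_worse" else 1.0
        noise = _skewed_noise(rng_tests, (n, n_visits), s.noise_sd, s.skew)
        test_cols[s.name] = s.offset + sign * s.loading * dom_obs[s.domain] + noise

    # --- frailty indicators -------------------------------------------
    ind_cols: dict[str, np.ndarray] = {}
    age_visit = ages[:, None] + months[None, :] / 12.0
    for s in config.indicator_schema:
        th_any = logit(min(s.p_any, 1 - 1e-9))
        th_sev = logit(max(s.p_severe, 1e-9))
        shift = (
            s.age_slope * (age_visit - config.age_mean)
            + survivor[:, None]
            * (s.survivor_lor_at_60 + s.survivor_lor_age_slope * (ages[:, None] - 60.0))
            + s.month_slope * months[None, :]
        )
        p_ge1 = expit(th_any + shift)
        p_ge2 = expit(th_sev + shift)
        u = rng_ind.random((n, n_visits))
        code = (u < p_ge1).astype(float) + (u < p_ge2)
        miss = rng_ind.random((n, n_visits)) < config.missing_rate
        code[miss] = np.nan
        ind_cols[s.name] = code

    # --- assemble long tables -----------------------------------------
    rows = observed.ravel()
    rep_pid = np.repeat(pid, n_visits)[rows]
    rep_grp = np.repeat(group, n_visits)[rows]
    rep_age = np.repeat(ages, n_visits)[rows]
    rep_month = np.tile(months, n)[rows]

    visits = pd.DataFrame(
        {"participant_id": rep_pid, "group": rep_grp,
         "age_enroll": rep_age, "month": rep_month}
    )
    for name, mat in test_cols.items():
        visits[name] = mat.ravel()[rows]

    indicators = pd.DataFrame({"participant_id": rep_pid, "month": rep_month})
    for name, mat in ind_cols.items():
        indicators[name] = mat.ravel()[rows]

    domain_truth = pd.DataFrame(
        {"participant_id": rep_pid, "group": rep_grp,
         "age_enroll": rep_age, "month": rep_month}
    )
    for d in domains:
        domain_truth[d] = dom_obs[d].ravel()[rows]

    truth = {
        "seed": int(config.seed if seed is None else seed),
        "center": float(config.age_mean),
        "quartile_bins": [list(b) for b in config.quartile_bins],
        "gammas": {d: config.gammas(d).as_dict() for d in domains},
        "sigma_alpha": sa, "sigma_beta": sb, "rho": rho, "sigma_eps": se,
        "n_survivors": config.n_survivors, "n_controls": config.n_controls,
        "latent": latent,
    }
    return Cohort(visits=visits, indicators=indicators, domain_truth=domain_truth,
                  truth=truth, config=config)
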