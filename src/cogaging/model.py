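"""Bayesian varying-intercepts, varying-slopes growth-curve model.

For participant *i* at visit *t* with outcome y (a domain z-score or a
frailty index) and m = months since baseline:

    level 1:  y_it = alpha_i + beta_i * m_it + eps_it,   eps ~ N(0, sigma_eps)

    level 2:  alpha_i = g00 + g01*c_i + g02*c_i^2
                        + S_i*(g03 + g04*c_i + g05*c_i^2) + u_i
              beta_i  = g10 + g11*S_i
                        + sum_k (g12_k + g13_k*S_i) * [Q_i = k] + v_i

where c_i is enrollment age centered at the sample mean, S_i indicates the
survivor cohort, Q_i is the baseline age quartile (youngest = reference),
and (u_i, v_i) are bivariate normal with covariance Omega parameterized by
(sigma_alpha, sigma_beta, rho).  The person intercept is the
*cross-sectional* score (first-assessment performance, free of practice
effects); the person slope is the *longitudinal* score, which absorbs
practice effects of repeated testing.

Inference is by a blocked Gibbs sampler with conjugate weakly-informative
priors: autoscaled Normal priors on the fixed effects, Inverse-Gamma on
the residual variance and Inverse-Wishart on Omega.  Convergence is
monitored with the split-chain potential-scale-reduction statistic
(R-hat <= 1.01 by default); intervals are 95% highest-density intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import InsufficientDataError, ValidationError
from .simulate import DEFAULT_QUARTILE_BINS, GAMMA_NAMES, assign_quartile

FIXED_NAMES = list(GAMMA_NAMES)
VARIANCE_NAMES = ["sigma_alpha", "sigma_beta", "rho", "sigma_eps"]
PARAM_NAMES = FIXED_NAMES + VARIANCE_NAMES

RHAT_THRESHOLD_DEFAULT = 1.01

MCMC_PRESETS = {
    # desk scale for tests and exploration
    "test": dict(chains=4, iterations=2000, warmup=500, thin=1),
    # the heavyweight production regime
    "paper": dict(chains=4, iterations=60_000, warmup=10_000, thin=5),
}


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------

@dataclass
class ModelInput:
    """Long-format design ready for the sampler."""

    y: np.ndarray  # (N,) outcome
    month: np.ndarray  # (N,) months since baseline
    pidx: np.ndarray  # (N,) 0-based participant index
    X: np.ndarray  # (N, 14) fixed-effect design, columns = FIXED_NAMES
    participant_ids: np.ndarray  # (n,) original ids in index order
    survivor: np.ndarray  # (n,) 0/1 per participant
    centered_age: np.ndarray  # (n,)
    quartile: np.ndarray  # (n,) 1..4
    center: float
    bins: tuple
    age_range: tuple[float, float]
    rejects: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_participants(self) -> int:
        return self.participant_ids.size


def build_design(
    panel: pd.DataFrame,
    outcome: str,
    bins: tuple = DEFAULT_QUARTILE_BINS,
    center: float | str = "auto",
) -> ModelInput:
    """Assemble a :class:`ModelInput` from a long participant-visit table.

    ``panel`` needs columns ``participant_id``, ``group`` (survivor /
    control or 1/0), ``age_enroll``, ``month`` and the outcome column.
    ``center="auto"`` centers age at the sample mean (over participants)
    rounded to 0.1 years.  Rows with a missing outcome are dropped;
    participants with missing age or group go to ``rejects``.
    """
    need = ["participant_id", "group", "age_enroll", "month", outcome]
    missing = [c for c in need if c not in panel.columns]
    if missing:
        raise ValidationError(f"panel is missing columns: {', '.join(missing)}")
    df = panel[need].copy()

    grp = df["group"]
    if grp.dtype == object:
        df["survivor"] = grp.map({"survivor": 1.0, "control": 0.0})
    else:
        df["survivor"] = grp.astype(float)

    bad = df["age_enroll"].isna() | df["survivor"].isna()
    rejects = df.loc[bad, ["participant_id", "group", "age_enroll"]].drop_duplicates()
    df = df.loc[~bad]
    df = df.loc[df[outcome].notna() & df["month"].notna()]
    if df.empty:
        raise InsufficientDataError("no usable observations after filtering")
    if (df["month"] < 0).any():
        raise ValidationError("month must be >= 0")

    people = (
        df.groupby("participant_id", sort=True)
        .agg(age=("age_enroll", "first"), survivor=("survivor", "first"))
    )
    if center == "auto":
        center_val = round(float(people["age"].mean()), 1)
    else:
        center_val = float(center)

    ids = people.index.to_numpy()
    code = {p: k for k, p in enumerate(ids)}
    pidx = df["participant_id"].map(code).to_numpy()

    c_person = people["age"].to_numpy() - center_val
    s_person = people["survivor"].to_numpy()
    q_person = assign_quartile(people["age"].to_numpy(), bins)

    m = df["month"].to_numpy(dtype=float)
    c = c_person[pidx]
    s = s_person[pidx]
    q = q_person[pidx]
    X = np.column_stack(
        [
            np.ones_like(m), c, c**2, s, s * c, s * c**2,
            m, s * m,
            m * (q == 2), m * (q == 3), m * (q == 4),
            s * m * (q == 2), s * m * (q == 3), s * m * (q == 4),
        ]
    )
    return ModelInput(
        y=df[outcome].to_numpy(dtype=float),
        month=m,
        pidx=pidx,
        X=X,
        participant_ids=ids,
        survivor=s_person,
        centered_age=c_person,
        quartile=q_person,
        center=center_val,
        bins=tuple(bins),
        age_range=(float(people["age"].min()), float(people["age"].max())),
        rejects=rejects,
    )


# --------------------------------------------------------------------------
# posterior summaries
# --------------------------------------------------------------------------

def hdi(draws: np.ndarray, prob: float = 0.95, min_draws: int = 100) -> tuple[float, float]:
    """Shortest contiguous interval containing ``prob`` of the draws.

    Ties in interval width break toward the lowest start.  Requires at
    least ``min_draws`` draws (set ``min_draws=1`` for degenerate inputs
    such as point-mass draws).
    """
    if not 0 < prob < 1:
        raise ValidationError(f"prob must lie in (0, 1); got {prob}")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < min_draws:
        raise InsufficientDataError(f"need >= {min_draws} draws, got {n}")
    m = math.ceil(prob * n)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    k = int(np.argmin(widths))  # argmin returns the first minimum: lowest start
    return float(x[k]), float(x[k + m - 1])


def rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction for one parameter.

    ``chains`` is (n_chains, n_draws); each chain is split in half, and
    the classic between/within variance ratio is returned.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValidationError("rhat needs a (n_chains >= 2, n_draws) array")
    n = arr.shape[1]
    if n < 4:
        raise InsufficientDataError("rhat needs at least 4 draws per chain")
    half = n // 2
    split = np.concatenate([arr[:, :half], arr[:, half: 2 * half]], axis=0)
    m, n = split.shape
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else float("inf")
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


@dataclass
class PosteriorSummary:
    """Posterior draws with summaries for the growth-curve model."""

    draws: dict[str, np.ndarray]  # name -> (n_chains, n_kept)
    summary: pd.DataFrame  # index: parameter; mean, hdi_lo, hdi_hi, rhat
    center: float
    bins: tuple
    age_range: tuple[float, float]
    rhat_threshold: float = RHAT_THRESHOLD_DEFAULT
    warnings: list[str] = field(default_factory=list)
    seed: int | None = None

    @property
    def converged(self) -> bool:
        return bool((self.summary["rhat"] <= self.rhat_threshold).all())

    def flat(self, name: str) -> np.ndarray:
        """All post-warmup draws of one parameter, chains concatenated."""
        return self.draws[name].ravel()

    @classmethod
    def from_point(cls, values: dict[str, float], center: float = 72.5,
                   bins: tuple = DEFAULT_QUARTILE_BINS,
                   age_range: tuple[float, float] = (60.0, 89.0)) -> "PosteriorSummary":
        """Point-mass posterior from fixed parameter values.

        Lets published posterior means be pushed through the same
        post-hoc machinery as full draws.
        """
        draws = {k: np.full((1, 1), float(v)) for k, v in values.items()}
        summary = pd.DataFrame(
            {"mean": values, "hdi_lo": values, "hdi_hi": values, "rhat": 1.0}
        )
        return cls(draws=draws, summary=summary, center=center, bins=bins,
                   age_range=age_range)


# --------------------------------------------------------------------------
# the Gibbs sampler
# --------------------------------------------------------------------------

def _default_priors(design: ModelInput) -> dict:
    """Weakly-informative priors autoscaled to the data, rstanarm-style.

    Fixed effects get Normal(0, 2.5 * sd(y) / sd(x_j)) (2.5 * sd(y) for the
    intercept and for degenerate columns); the residual variance gets
    InvGamma(1, sd(y)^2 / 2); Omega gets InvWishart(nu0 = 3, 0.01 * diag
    scaled to the outcome and the month span).
    """
    sy = float(np.std(design.y)) or 1.0
    sx = design.X.std(axis=0)
    gamma_sd = np.where(sx > 0, 2.5 * sy / np.where(sx > 0, sx, 1.0), 2.5 * sy)
    gamma_sd[0] = 2.5 * sy
    m_span = float(np.ptp(design.month)) or 1.0
    S0 = 0.01 * np.diag([sy**2, (sy / m_span) ** 2])
    return {
        "gamma_mean": np.zeros(design.X.shape[1]),
        "gamma_sd": gamma_sd,
        "eps_a0": 1.0,
        "eps_b0": sy**2 / 2.0,
        "omega_nu0": 3.0,
        "omega_S0": S0,
    }


def _invwishart_2x2(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw from InvWishart(df, scale) for a 2x2 scale matrix.

    Bartlett decomposition of W ~ Wishart(df, scale^-1), then a closed-form
    2x2 inverse; equivalent to scipy.stats.invwishart.rvs but without the
    per-call overhead.
    """
    s11, s12, s22 = scale[0, 0], scale[0, 1], scale[1, 1]
    sdet = s11 * s22 - s12 * s12
    # chol of scale^-1 = [[c11, 0], [c21, c22]]
    i11, i12, i22 = s22 / sdet, -s12 / sdet, s11 / sdet
    c11 = np.sqrt(i11)
    c21 = i12 / c11
    c22 = np.sqrt(i22 - c21 * c21)
    a11 = np.sqrt(rng.chisquare(df))
    a22 = np.sqrt(rng.chisquare(df - 1.0))
    a21 = rng.standard_normal()
    # L = C @ A (both lower triangular), W = L L'
    l11 = c11 * a11
    l21 = c21 * a11 + c22 * a21
    l22 = c22 * a22
    w11 = l11 * l11
    w12 = l11 * l21
    w22 = l21 * l21 + l22 * l22
    wdet = w11 * w22 - w12 * w12
    return np.array([[w22 / wdet, -w12 / wdet], [-w12 / wdet, w11 / wdet]])


def _run_chain(design: ModelInput, priors: dict, n_iter: int, warmup: int,
               thin: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    y, X, m, pidx = design.y, design.X, design.month, design.pidx
    n_obs, p = X.shape
    n = design.n_participants

    XtX = X.T @ X
    prior_prec = np.diag(1.0 / priors["gamma_sd"] ** 2)
    n_i = np.bincount(pidx, minlength=n).astype(float)
    Sm = np.bincount(pidx, weights=m, minlength=n)
    Smm = np.bincount(pidx, weights=m * m, minlength=n)
    # per-person X'Z blocks for the collapsed fixed-effect update:
    # G[i] = [sum_t x_it, sum_t m_it x_it]  (p x 2)
    Sx = np.zeros((n, p))
    Smx = np.zeros((n, p))
    np.add.at(Sx, pidx, X)
    np.add.at(Smx, pidx, m[:, None] * X)
    G = np.stack([Sx, Smx], axis=2)  # (n, p, 2)

    # initial state
    gamma = np.zeros(p)
    u = np.zeros(n)
    v = np.zeros(n)
    sig_eps2 = max(float(np.var(y)), 1e-6)
    Omega = np.diag([max(sig_eps2, 1e-4), max(sig_eps2, 1e-4) / 100.0])

    kept = (n_iter - warmup) // thin
    out = {name: np.empty(kept) for name in PARAM_NAMES}
    k_out = 0

    nu0, S0 = priors["omega_nu0"], priors["omega_S0"]
    a0, b0 = priors["eps_a0"], priors["eps_b0"]

    Xty = X.T @ y
    Sy = np.bincount(pidx, weights=y, minlength=n)
    Smy = np.bincount(pidx, weights=m * y, minlength=n)

    for it in range(n_iter):
        # --- gamma | Omega, sigma_eps (random effects integrated out) ---
        # marginal cov per person: sigma_eps^2 I + Z_i Omega Z_i';
        # Woodbury gives X'V^-1 X = [X'X - sum_i G_i K_i^-1 G_i'] / s2
        # with K_i = s2 * Omega^-1 + Z_i'Z_i (2x2, closed-form inverse)
        Oinv = np.linalg.inv(Omega)
        kA = sig_eps2 * Oinv[0, 0] + n_i
        kB = sig_eps2 * Oinv[0, 1] + Sm
        kC = sig_eps2 * Oinv[1, 1] + Smm
        kdet = kA * kC - kB * kB
        Kinv = np.empty((n, 2, 2))
        Kinv[:, 0, 0] = kC / kdet
        Kinv[:, 0, 1] = Kinv[:, 1, 0] = -kB / kdet
        Kinv[:, 1, 1] = kA / kdet
        GK = np.matmul(G, Kinv)  # (n, p, 2)
        GKr = GK.transpose(0, 2, 1).reshape(2 * n, p)
        Gr = G.transpose(0, 2, 1).reshape(2 * n, p)
        XtVX = (XtX - GKr.T @ Gr) / sig_eps2
        zty = np.column_stack([Sy, Smy])  # (n, 2)
        XtVy = (Xty - GKr.T @ zty.reshape(2 * n)) / sig_eps2
        prec = XtVX + prior_prec
        L = np.linalg.cholesky(prec)
        rhs = XtVy + prior_prec @ priors["gamma_mean"]
        mean = np.linalg.solve(prec, rhs)
        gamma = mean + np.linalg.solve(L.T, rng.standard_normal(p))

        # --- random effects (u_i, v_i) | gamma, closed-form bivariate normal ---
        r = y - X @ gamma
        Sr = np.bincount(pidx, weights=r, minlength=n)
        Smr = np.bincount(pidx, weights=m * r, minlength=n)
        A = Oinv[0, 0] + n_i / sig_eps2
        B = Oinv[0, 1] + Sm / sig_eps2
        C = Oinv[1, 1] + Smm / sig_eps2
        det = A * C - B * B
        h1 = Sr / sig_eps2
        h2 = Smr / sig_eps2
        mu_u = (C * h1 - B * h2) / det
        mu_v = (A * h2 - B * h1) / det
        L11 = np.sqrt(C / det)
        L21 = -B / (det * L11)
        L22 = np.sqrt(np.maximum(A / det - L21**2, 1e-300))
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        u = mu_u + L11 * z1
        v = mu_v + L21 * z1 + L22 * z2

        # --- Omega | b ---
        bmat = np.column_stack([u, v])
        scale = S0 + bmat.T @ bmat
        Omega = _invwishart_2x2(nu0 + n, scale, rng)

        # --- residual variance | gamma, b ---
        r2 = y - u[pidx] - m * v[pidx]

        e = r2 - X @ gamma
        sig_eps2 = 1.0 / rng.gamma(a0 + n_obs / 2.0, 1.0 / (b0 + e @ e / 2.0))
        sig_eps2 = max(sig_eps2, 1e-12)

        if it >= warmup and (it - warmup) % thin == 0 and k_out < kept:
            for j, name in enumerate(FIXED_NAMES):
                out[name][k_out] = gamma[j]
            sa = np.sqrt(Omega[0, 0])
            sb = np.sqrt(Omega[1, 1])
            out["sigma_alpha"][k_out] = sa
            out["sigma_beta"][k_out] = sb
            out["rho"][k_out] = Omega[0, 1] / (sa * sb)
            out["sigma_eps"][k_out] = np.sqrt(sig_eps2)
            k_out += 1
    return out


class GrowthCurveModel(BaseEstimator):
    """Varying-intercepts, varying-slopes Bayesian growth-curve estimator.

    scikit-learn style: construct with sampler settings, call
    :meth:`fit` on a long participant-visit table (or a prebuilt
    :class:`ModelInput`), then read fitted attributes.

    Parameters
    ----------
    outcome : str
        Outcome column name used when fit is given a DataFrame.
    preset : {"test", "paper", None}
        Named MCMC regimes; explicit chains/iterations/warmup/thin
        override the preset.
    center : float or "auto"
        Age-centering constant; "auto" uses the sample mean age.
    bins : tuple of (lo, hi)
        Baseline age-quartile bins.
    priors : dict or None
        Overrides for the autoscaled prior hyperparameters.
    rhat_threshold : float
        Convergence criterion carried into the result.
    random_state : int or None
        Sampler seed; chains derive independent streams from it.

    Attributes
    ----------
    posterior_ : PosteriorSummary
    summary_ : pandas.DataFrame
        Per-parameter posterior mean, 95% HDI and split R-hat.
    converged_ : bool
    warnings_ : list of str
    """

    def __init__(
        self,
        outcome: str = "APE",
        preset: str | None = "test",
        chains: int | None = None,
        iterations: int | None = None,
        warmup: int | None = None,
        thin: int | None = None,
        center: float | str = "auto",
        bins: tuple = DEFAULT_QUARTILE_BINS,
        priors: dict | None = None,
        hdi_prob: float = 0.95,
        rhat_threshold: float = RHAT_THRESHOLD_DEFAULT,
        random_state: int | None = None,
    ):
        self.outcome = outcome
        self.preset = preset
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.thin = thin
        self.center = center
        self.bins = bins
        self.priors = priors
        self.hdi_prob = hdi_prob
        self.rhat_threshold = rhat_threshold
        self.random_state = random_state

    def _mcmc_settings(self) -> dict:
        base = dict(MCMC_PRESETS.get(self.preset or "", MCMC_PRESETS["test"]))
        for key in ("chains", "iterations", "warmup", "thin"):
            val = getattr(self, key)
            if val is not None:
                base[key] = int(val)
        if base["chains"] < 2:
            raise ValidationError("at least 2 chains are required")
        if base["warmup"] >= base["iterations"]:
            raise ValidationError("warmup must be < iterations")
        return base

    def fit(self, X: pd.DataFrame | ModelInput, y=None) -> "GrowthCurveModel":
        design = (
            X if isinstance(X, ModelInput)
            else build_design(X, self.outcome, bins=self.bins, center=self.center)
        )
        settings = self._mcmc_settings()
        priors = _default_priors(design)
        if self.priors:
            priors.update(self.priors)

        notes: list[str] = []
        if np.unique(design.month).size < 2:
            notes.append(
                "single-visit data: slope block (g10..g13_4, sigma_beta, rho) "
                "is not identified and reverts to its prior"
            )
        degenerate = [
            FIXED_NAMES[j] for j in range(1, design.X.shape[1])
            if design.X[:, j].std() == 0
        ]
        if degenerate:
            notes.append(
                "degenerate design columns held at their prior: " + ", ".join(degenerate)
            )

        root = np.random.SeedSequence(self.random_state)
        chain_draws = [
            _run_chain(design, priors, settings["iterations"], settings["warmup"],
                       settings["thin"], np.random.default_rng(s))
            for s in root.spawn(settings["chains"])
        ]
        draws = {
            name: np.stack([ch[name] for ch in chain_draws])
            for name in PARAM_NAMES
        }

        rows = {}
        for name in PARAM_NAMES:
            flat = draws[name].ravel()
            lo, hi = hdi(flat, self.hdi_prob, min_draws=4)
            rows[name] = {
                "mean": float(flat.mean()),
                "hdi_lo": lo,
                "hdi_hi": hi,
                "rhat": rhat(draws[name]),
            }
        summary = pd.DataFrame.from_dict(rows, orient="index").loc[PARAM_NAMES]

        bad = summary.index[summary["rhat"] > self.rhat_threshold].tolist()
        if bad:
            msg = (
                f"convergence warning: R-hat > {self.rhat_threshold} for "
                + ", ".join(bad)
            )
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)

        self.design_ = design
        self.posterior_ = PosteriorSummary(
            draws=draws, summary=summary, center=design.center, bins=design.bins,
            age_range=design.age_range, rhat_threshold=self.rhat_threshold,
            warnings=notes, seed=self.random_state,
        )
        self.summary_ = summary
        self.converged_ = self.posterior_.converged
        self.warnings_ = notes
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean fixed-effect prediction for new participant-visits.

        Uses the population-level (fixed) structure only; person-level
        deviations are integrated out (set to their zero prior mean).
        """
        design = build_design(X, self.outcome, bins=self.bins, center=self.posterior_.center)
        gamma = self.summary_.loc[FIXED_NAMES, "mean"].to_numpy()
        return design.X @ gamma


def fit_model(
    panel: pd.DataFrame,
    outcome: str = "APE",
    preset: str = "test",
    random_state: int | None = None,
    **kwargs,
) -> PosteriorSummary:
    """Functional wrapper: fit the growth-curve model, return its posterior."""
    est = GrowthCurveModel(outcome=outcome, preset=preset,
                           random_state=random_state, **kwargs)
    est.fit(panel)
    return est.posterior_
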