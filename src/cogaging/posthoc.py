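"""Derived quantities from the fitted growth-curve posterior.

* per-decade conversion of per-year age coefficients,
* the survivor-minus-control gap curve over an age grid, with a per-age
  95% HDI band computed from the draw-level gap distribution (so posterior
  correlations between the three group-difference coefficients are
  respected),
* the null-crossing age: scanning the grid in ascending age, the first
  age at which the band contains zero — the age beyond which the cohort
  difference is no longer credibly different from zero,
* trajectory panels: cross-sectional quadratic age curves per cohort with
  credible bands, plus per-quartile longitudinal practice-effect segments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import FIXED_NAMES, ModelInput, PosteriorSummary, hdi
from .simulate import GammaVector, level2_intercept, level2_slope

logger = logging.getLogger(__name__)

DEFAULT_GRID = np.round(np.arange(60.0, 89.0 + 1e-9, 0.1), 1)


def per_decade_effect(gamma_linear: float) -> float:
    """Convert a per-year linear age coefficient to its per-decade effect.

    Returns the signed value; reporting layers may show the magnitude
    (e.g. a coefficient of -0.047 per year is a 0.47 z-score decline per
    decade of aging).
    """
    if not np.isfinite(gamma_linear):
        raise ValidationError("coefficient must be finite")
    return 10.0 * float(gamma_linear)


@dataclass
class GapCurve:
    """Survivor-minus-control difference over age with its credible band."""

    ages: np.ndarray
    mean_diff: np.ndarray
    hdi_lo: np.ndarray
    hdi_hi: np.ndarray
    significant: np.ndarray  # True where the band excludes 0
    crossing_age: float | None
    crossing_flag: str | None = None  # "contains_null_at_start" | "never_contains_null"
    extrapolated: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"age": self.ages, "mean": self.mean_diff,
             "hdi_lo": self.hdi_lo, "hdi_hi": self.hdi_hi,
             "significant": self.significant}
        )
        if self.extrapolated is not None:
            df["extrapolated"] = self.extrapolated
        return df


def gap_curve(
    posterior: PosteriorSummary,
    ages: np.ndarray = DEFAULT_GRID,
    center: float | None = None,
    prob: float = 0.95,
) -> GapCurve:
    """Posterior survivor-minus-control gap over an age grid.

    Per draw and age a:  diff(a) = g03 + g04*(a - center) + g05*(a - center)^2.
    The band is the per-age HDI of that draw-level distribution.
    """
    for name in ("g03", "g04", "g05"):
        if name not in posterior.draws:
            raise ValidationError(f"posterior lacks draws for {name}")
    ages = np.asarray(ages, dtype=float)
    center = posterior.center if center is None else float(center)
    c = ages - center
    g03 = posterior.flat("g03")[:, None]
    g04 = posterior.flat("g04")[:, None]
    g05 = posterior.flat("g05")[:, None]
    diff = g03 + g04 * c[None, :] + g05 * c[None, :] ** 2  # (draws, ages)

    mean = diff.mean(axis=0)
    if diff.shape[0] == 1:
        lo = hi = mean.copy()
    else:
        bands = np.array([hdi(diff[:, j], prob, min_draws=2) for j in range(ages.size)])
        lo, hi = bands[:, 0], bands[:, 1]
    significant = (lo > 0) | (hi < 0)

    lo_obs, hi_obs = posterior.age_range
    extrapolated = (ages < lo_obs) | (ages > hi_obs)
    if extrapolated.any():
        logger.warning(
            "gap curve evaluated outside the observed age range [%.1f, %.1f] "
            "at %d grid points", lo_obs, hi_obs, int(extrapolated.sum()),
        )

    curve = GapCurve(
        ages=ages, mean_diff=mean, hdi_lo=lo, hdi_hi=hi,
        significant=significant, crossing_age=None, extrapolated=extrapolated,
    )
    curve.crossing_age, curve.crossing_flag = crossing_age(curve, with_flag=True)
    return curve


def crossing_age(curve: GapCurve, with_flag: bool = False):
    """First age (ascending) at which the credible band contains zero.

    Returns ``None`` when the band excludes zero everywhere.  When the
    band already contains zero at the grid start, the grid start is
    returned with the flag ``"contains_null_at_start"``.
    """
    contains = ~curve.significant
    if not contains.any():
        return (None, "never_contains_null") if with_flag else None
    k = int(np.argmax(contains))
    flag = "contains_null_at_start" if k == 0 else None
    age = float(curve.ages[k])
    return (age, flag) if with_flag else age


def significance_intervals(curve: GapCurve) -> list[tuple[float, float]]:
    """Maximal age intervals over which the band excludes zero.

    Recovers window-style findings (a gap significant only between two
    ages) from the boolean significance vector.
    """
    sig = np.asarray(curve.significant, bool)
    out = []
    k = 0
    while k < sig.size:
        if sig[k]:
            start = k
            while k < sig.size and sig[k]:
                k += 1
            out.append((float(curve.ages[start]), float(curve.ages[k - 1])))
        else:
            k += 1
    return out


def write_gap_report(curve: GapCurve, outdir: str | Path, name: str) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"gap_curve_{name}.csv"
    curve.to_frame().to_csv(csv_path, index=False)
    report = {
        "outcome": name,
        "crossing_age": curve.crossing_age,
        "crossing_flag": curve.crossing_flag,
        "significant_age_intervals": significance_intervals(curve),
    }
    json_path = outdir / f"crossing_{name}.json"
    json_path.write_text(json.dumps(report, indent=2))
    return {"curve": csv_path, "report": json_path}


# --------------------------------------------------------------------------
# trajectory figure
# --------------------------------------------------------------------------

def _posterior_gamma_matrix(posterior: PosteriorSummary) -> np.ndarray:
    return np.column_stack([posterior.flat(n) for n in FIXED_NAMES])


def trajectory_panel(
    posterior: PosteriorSummary,
    design: ModelInput,
    outpath: str | Path,
    outcome: str = "outcome",
    ages: np.ndarray = DEFAULT_GRID,
    prob: float = 0.95,
    truth: GammaVector | None = None,
):
    """Render the two-panel trajectory figure for one outcome.

    Left: model-estimated cross-sectional (first-assessment) scores over
    age per cohort with credible bands, plus per-quartile longitudinal
    segments over the study months.  Right: the survivor-minus-control
    gap curve with its band and null-crossing annotation.  Optionally
    overlays the generating truth for synthetic cohorts.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not posterior.draws:
        raise ValidationError("posterior carries no draws")
    gammas = _posterior_gamma_matrix(posterior)  # (draws, 14)
    center = posterior.center
    c = ages - center
    fig, (ax_l, ax_r) = plt.subplots(1, 2, figsize=(11, 4.5))

    months_max = float(design.month.max()) if design.month.size else 24.0
    colors = {0.0: "tab:blue", 1.0: "tab:red"}
    labels = {0.0: "control", 1.0: "survivor"}
    for s_val in (0.0, 1.0):
        # cross-sectional quadratic per cohort
        basis = np.column_stack(
            [np.ones_like(c), c, c**2,
             np.full_like(c, s_val), s_val * c, s_val * c**2]
        )
        curves = gammas[:, :6] @ basis.T  # (draws, ages)
        mean = curves.mean(axis=0)
        if curves.shape[0] > 1:
            band = np.array([hdi(curves[:, j], prob, min_draws=2) for j in range(ages.size)])
            ax_l.fill_between(ages, band[:, 0], band[:, 1], alpha=0.2,
                              color=colors[s_val], lw=0)
        ax_l.plot(ages, mean, color=colors[s_val], label=labels[s_val])

        # per-quartile longitudinal segments at the quartile mean age
        gmean = gammas.mean(axis=0)
        gv = GammaVector(**dict(zip(FIXED_NAMES, gmean)))
        for k, (b_lo, b_hi) in enumerate(design.bins, start=1):
            in_q = (design.quartile == k) & (design.survivor == s_val)
            if not in_q.any():
                logger.info("quartile %d has no %s participants; segment omitted",
                            k, labels[s_val])
                continue
            age_q = float(design.centered_age[in_q].mean()) + center
            seg_months = np.linspace(0.0, months_max, 9)
            alpha0 = level2_intercept(gv, np.array([age_q - center]),
                                      np.array([s_val]))[0]
            slope = level2_slope(gv, np.array([k]), np.array([s_val]))[0]
            yy = alpha0 + slope * seg_months
            xx = age_q + seg_months / 12.0
            ax_l.plot(xx, yy, marker="o", ms=2.5, lw=1.2, color=colors[s_val],
                      alpha=0.8)
    ax_l.set_xlabel("age (years)")
    ax_l.set_ylabel(outcome)
    ax_l.set_title(f"model-estimated {outcome} over age")
    ax_l.legend()

    curve = gap_curve(posterior, ages)
    ax_r.fill_between(curve.ages, curve.hdi_lo, curve.hdi_hi, alpha=0.25,
                      color="tab:purple", lw=0)
    ax_r.plot(curve.ages, curve.mean_diff, color="tab:purple")
    if truth is not None:
        cc = ages - center
        ax_r.plot(ages, truth.g03 + truth.g04 * cc + truth.g05 * cc**2,
                  "k--", lw=1, label="generating truth")
        ax_r.legend()
    ax_r.axhline(0.0, color="gray", lw=0.8)
    if curve.crossing_age is not None:
        ax_r.axvline(curve.crossing_age, color="gray", ls=":", lw=1)
        ax_r.annotate(f"null-crossing {curve.crossing_age:.1f}",
                      (curve.crossing_age, 0), textcoords="offset points",
                      xytext=(5, 8), fontsize=8)
    ax_r.set_xlabel("age (years)")
    ax_r.set_ylabel(f"survivor − control {outcome}")
    ax_r.set_title("cohort gap with 95% HDI band")

    fig.tight_layout()
    outpath = Path(outpath)
    outpath.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(outpath, dpi=150)
    plt.close(fig)
    return outpath
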