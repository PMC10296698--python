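"""Neuropsychological domain scoring.

Raw test scores are converted into two domain composites —

* **APE**: attention, processing speed and executive function
* **LM**: learning and memory

— in four steps.  Each test is (1) checked for deviation from normality
(absolute sample skewness above a threshold, default 1.0); (2) if
non-normal, Box–Cox power-transformed with a shift so all values are
positive, the exponent chosen by profile-likelihood grid search over
[-3, 3]; (3) z-standardized against a reference sample of healthy controls
at their first (baseline) visit, with timed "higher is worse" tests negated
so that larger z always means better performance; and (4) averaged within
domain per participant-visit, the composite being reported only when at
least half of the domain's member tests are present.

The reference population defines the scale: transformation parameters and
reference moments are estimated once on baseline controls and then applied
unchanged to every visit of every participant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InsufficientDataError, ValidationError

DOMAINS = ("APE", "LM")

SKEW_THRESHOLD_DEFAULT = 1.0
MIN_NORMALITY_N = 20


@dataclass(frozen=True)
class TestSchema:
    """One test's domain membership and scoring direction."""

    name: str
    domain: str  # "APE" or "LM"
    direction: str = "higher_better"  # or "higher_worse"

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise ValidationError(f"unknown domain {self.domain!r} for test {self.name!r}")
        if self.direction not in ("higher_better", "higher_worse"):
            raise ValidationError(f"unknown direction {self.direction!r}")


# Default battery.  Timed tests (Trails, color-word naming) score time to
# completion, so a higher raw value is worse.
DEFAULT_BATTERY: tuple[TestSchema, ...] = (
    TestSchema("digit_symbol", "APE", "higher_better"),
    TestSchema("trail_making_a", "APE", "higher_worse"),
    TestSchema("trail_making_b", "APE", "higher_worse"),
    TestSchema("dkefs_color_word", "APE", "higher_worse"),
    TestSchema("nab_digits_forward", "APE", "higher_better"),
    TestSchema("nab_digits_backward", "APE", "higher_better"),
    TestSchema("nab_driving_scenes", "APE", "higher_better"),
    TestSchema("nab_ll_trial1", "LM", "higher_better"),
    TestSchema("nab_ll_semantic_clustering", "LM", "higher_better"),
    TestSchema("nab_ll_list_a_immediate", "LM", "higher_better"),
    TestSchema("nab_ll_list_a_delayed", "LM", "higher_better"),
    TestSchema("nab_ll_long_delay", "LM", "higher_better"),
    TestSchema("nab_ll_list_b_immediate", "LM", "higher_better"),
    TestSchema("nab_ll_recognition", "LM", "higher_better"),
    TestSchema("logical_memory_1", "LM", "higher_better"),
    TestSchema("logical_memory_2", "LM", "higher_better"),
)


def battery_by_domain(battery: Sequence[TestSchema]) -> dict[str, list[TestSchema]]:
    out: dict[str, list[TestSchema]] = {d: [] for d in DOMAINS}
    seen: set[str] = set()
    for t in battery:
        if t.name in seen:
            raise ValidationError(f"test {t.name!r} appears twice in the battery")
        seen.add(t.name)
        out[t.domain].append(t)
    return out


def assess_normality(
    values: Sequence[float] | np.ndarray,
    threshold: float = SKEW_THRESHOLD_DEFAULT,
) -> str:
    """Classify a sample as ``"normal"`` or ``"non_normal"`` by skewness.

    Returns ``"non_normal"`` iff |sample skewness| > ``threshold``.
    Requires at least 20 non-missing values and non-zero variance.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < MIN_NORMALITY_N:
        raise InsufficientDataError(
            f"need >= {MIN_NORMALITY_N} values to assess normality, got {arr.size}"
        )
    if np.std(arr) == 0:
        raise InsufficientDataError("skewness undefined for a zero-variance sample")
    return "non_normal" if abs(stats.skew(arr)) > threshold else "normal"


@dataclass(frozen=True)
class BoxCoxParams:
    """Fitted power-transform: x -> ((x + shift)^lmbda - 1) / lmbda."""

    lmbda: float
    shift: float = 0.0


def fit_boxcox(
    values: Sequence[float] | np.ndarray,
    grid: tuple[float, float, float] = (-3.0, 3.0, 0.01),
) -> BoxCoxParams:
    """Fit a Box–Cox exponent by profile-likelihood grid search.

    If any value is non-positive, a shift of ``1 - min(values)`` is applied
    first so the minimum becomes 1.  The exponent maximizing the Box–Cox
    log-likelihood over the grid is returned.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2 or np.std(arr) == 0:
        raise InsufficientDataError("Box–Cox requires a non-degenerate sample")
    shift = 0.0
    if arr.min() <= 0:
        shift = 1.0 - arr.min()
        arr = arr + shift
    lo, hi, step = grid
    lambdas = np.arange(lo, hi + step / 2, step)
    llf = np.array([stats.boxcox_llf(l, arr) for l in lambdas])
    return BoxCoxParams(lmbda=float(lambdas[np.argmax(llf)]), shift=shift)


def apply_boxcox(values: np.ndarray | pd.Series, params: BoxCoxParams) -> np.ndarray:
    arr = np.asarray(values, dtype=float) + params.shift
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    pos = ok & (arr > 0)
    # values pushed <= 0 by out-of-sample data stay missing rather than
    # producing complex powers
    if params.lmbda == 0:
        out[pos] = np.log(arr[pos])
    else:
        out[pos] = (np.power(arr[pos], params.lmbda) - 1.0) / params.lmbda
    return out


@dataclass(frozen=True)
class TestReference:
    """Per-test standardization: transform parameters + reference moments."""

    transform: BoxCoxParams | None
    mean: float
    sd: float


class StandardizationReference(dict):
    """Mapping test name -> :class:`TestReference` fitted on baseline controls."""


def standardize(
    df: pd.DataFrame,
    reference: Mapping[str, TestReference],
    battery: Sequence[TestSchema] = DEFAULT_BATTERY,
) -> pd.DataFrame:
    """Standardize raw test columns to control-referenced z-scores.

    z = (transformed value - reference mean) / reference SD, negated for
    ``higher_worse`` tests so that higher z is always better.
    """
    out = {}
    for t in battery:
        if t.name not in df.columns:
            continue
        if t.name not in reference:
            raise ValidationError(f"test {t.name!r} absent from the standardization reference")
        ref = reference[t.name]
        x = df[t.name].to_numpy(dtype=float)
        if ref.transform is not None:
            x = apply_boxcox(x, ref.transform)
        z = (x - ref.mean) / ref.sd
        if t.direction == "higher_worse":
            z = -z
        out[t.name] = z
    return pd.DataFrame(out, index=df.index)


def domain_scores(
    zdf: pd.DataFrame,
    battery: Sequence[TestSchema] = DEFAULT_BATTERY,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Average member-test z-scores into per-row domain composites.

    A composite is reported only when at least ``ceil(min_fraction * n)``
    of the domain's ``n`` member tests are present in that row.
    """
    by_dom = battery_by_domain(battery)
    out = pd.DataFrame(index=zdf.index)
    for dom, tests in by_dom.items():
        cols = [t.name for t in tests if t.name in zdf.columns]
        if not cols:
            out[dom] = np.nan
            out[f"n_tests_{dom}"] = 0
            continue
        block = zdf[cols]
        n_present = block.notna().sum(axis=1)
        need = math.ceil(min_fraction * len(tests))
        score = block.mean(axis=1)
        score[n_present < need] = np.nan
        out[dom] = score
        out[f"n_tests_{dom}"] = n_present
    return out


class DomainScorer(BaseEstimator, TransformerMixin):
    """Control-referenced domain scorer (fit on baseline controls).

    ``fit`` learns, per test: whether a Box–Cox transform is needed
    (absolute skewness above ``skew_threshold``), its parameters, and the
    reference mean/SD of the (possibly transformed) baseline control
    values.  ``transform`` maps any visit table to z-scores on that fixed
    scale; :meth:`score_panel` additionally averages z-scores into APE and
    LM composites.

    Parameters
    ----------
    battery : sequence of TestSchema
        Tests with domain membership and direction; defaults to the
        standard 7-test APE / 9-test LM battery.
    skew_threshold : float
        |skewness| above which a test is transformed before standardizing.
    min_fraction : float
        Minimum fraction of a domain's tests required for its composite.
    use_boxcox : bool
        Disable to standardize raw scores directly (lambda = 1 forced).
    """

    def __init__(
        self,
        battery: Sequence[TestSchema] = DEFAULT_BATTERY,
        skew_threshold: float = SKEW_THRESHOLD_DEFAULT,
        min_fraction: float = 0.5,
        use_boxcox: bool = True,
        boxcox_grid: tuple[float, float, float] = (-3.0, 3.0, 0.01),
    ):
        self.battery = battery
        self.skew_threshold = skew_threshold
        self.min_fraction = min_fraction
        self.use_boxcox = use_boxcox
        self.boxcox_grid = boxcox_grid

    def fit(self, X: pd.DataFrame, y=None) -> "DomainScorer":
        """Fit the standardization reference on baseline control rows."""
        reference = StandardizationReference()
        for t in self.battery:
            if t.name not in X.columns:
                continue
            vals = X[t.name].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size < MIN_NORMALITY_N:
                raise InsufficientDataError(
                    f"test {t.name!r}: {vals.size} reference values, need {MIN_NORMALITY_N}"
                )
            if np.std(vals) == 0:
                raise ValidationError(f"test {t.name!r}: zero variance in reference sample")
            params = None
            if self.use_boxcox and assess_normality(vals, self.skew_threshold) == "non_normal":
                params = fit_boxcox(vals, self.boxcox_grid)
                vals = apply_boxcox(vals, params)
            reference[t.name] = TestReference(
                transform=params, mean=float(np.mean(vals)), sd=float(np.std(vals, ddof=1))
            )
        if not reference:
            raise ValidationError("no battery test columns found in the reference table")
        self.reference_ = reference
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return control-referenced z-scores for the battery columns."""
        return standardize(X, self.reference_, self.battery)

    def score_panel(
        self, X: pd.DataFrame, id_cols: Sequence[str] = ("participant_id", "month")
    ) -> pd.DataFrame:
        """z-score then average into an APE/LM domain panel.

        Carries ``id_cols`` through from ``X`` so the result is a tidy
        participant-visit table.
        """
        z = self.transform(X)
        panel = domain_scores(z, self.battery, self.min_fraction)
        carried = [c for c in id_cols if c in X.columns]
        if carried:
            panel = pd.concat([X[carried].reset_index(drop=True),
                               panel.reset_index(drop=True)], axis=1)
        return panel
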