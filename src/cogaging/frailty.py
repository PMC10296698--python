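"""Deficit Accumulation Frailty Index (DAFI).

The index summarizes up to 44 ordinal frailty indicators, each coded
0 (risk absent), 1 (intermediate) or 2 (most adverse), as

    DAFI = sum(non-missing codes) / (2 * n_assessed)

so it lives on [0, 1].  A missing indicator is dropped from both the
numerator and the denominator.  The score is considered valid only when at
least ``min_assessed`` indicators (default 35) were assessed; otherwise the
result is flagged invalid.  Continuous scores map onto three clinical
categories: robust (< 0.2), pre-frail ([0.2, 0.35)) and frail (>= 0.35).

Indicators that are excluded by design (for example a self-report of
cognitive function, or the cancer history that defines the cohorts) never
enter the numerator or denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ValidationError

N_INDICATORS = 44
MIN_ASSESSED_DEFAULT = 35

ROBUST_CUT = 0.2
FRAIL_CUT = 0.35

CATEGORIES = ("robust", "pre_frail", "frail")


@dataclass(frozen=True)
class DafiResult:
    """Frailty index for one assessment.

    ``score`` is NaN and ``category`` is ``"invalid"`` when fewer than the
    required number of indicators were assessed.
    """

    score: float
    n_assessed: int
    category: str

    @property
    def valid(self) -> bool:
        return self.category != "invalid"


@dataclass(frozen=True)
class IndicatorSchema:
    """Names and design-exclusion flags for an indicator battery."""

    labels: tuple[str, ...] = field(
        default_factory=lambda: tuple(f"i{k:02d}" for k in range(1, N_INDICATORS + 1))
    )
    excluded: frozenset[str] = frozenset()

    def included_positions(self) -> list[int]:
        return [k for k, lab in enumerate(self.labels) if lab not in self.excluded]


def _clean(values: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(
        [np.nan if v is None else float(v) for v in values], dtype=float
    )
    finite = arr[~np.isnan(arr)]
    if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
        bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
        raise ValidationError(
            f"indicator values must be 0, 1, 2 or missing; found {bad[0]!r}"
        )
    return arr


def categorize(score: float) -> str:
    """Map a valid DAFI score onto robust / pre_frail / frail.

    Cut-offs are half-open: [0, 0.2) robust, [0.2, 0.35) pre-frail,
    [0.35, 1] frail.
    """
    if math.isnan(score) or score < 0 or score > 1:
        raise ValidationError(f"DAFI score must lie in [0, 1]; got {score!r}")
    if score < ROBUST_CUT:
        return "robust"
    if score < FRAIL_CUT:
        return "pre_frail"
    return "frail"


def score_dafi(
    values: Sequence[float] | np.ndarray,
    min_assessed: int = MIN_ASSESSED_DEFAULT,
    excluded_positions: Iterable[int] = (),
) -> DafiResult:
    """Compute the deficit-accumulation frailty index for one vector.

    Parameters
    ----------
    values
        Ordered indicator codes; each entry 0, 1, 2, ``None`` or NaN.
    min_assessed
        Minimum number of assessed (non-missing, non-excluded) indicators
        for the score to count as valid.
    excluded_positions
        0-based positions excluded by design; they never enter the score.
    """
    arr = _clean(values)
    keep = np.ones(arr.size, dtype=bool)
    for pos in excluded_positions:
        keep[pos] = False
    arr = arr[keep]
    assessed = ~np.isnan(arr)
    n_assessed = int(assessed.sum())
    if n_assessed < min_assessed:
        return DafiResult(score=float("nan"), n_assessed=n_assessed, category="invalid")
    score = float(arr[assessed].sum()) / (2.0 * n_assessed)
    return DafiResult(score=score, n_assessed=n_assessed, category=categorize(score))


class FrailtyIndex(BaseEstimator, TransformerMixin):
    """Stateless transformer computing per-row DAFI scores from a table.

    Operates on a DataFrame whose indicator columns are named by
    ``schema.labels`` (default ``i01`` .. ``i44``); any other columns (ids,
    visit month) pass through untouched.  ``transform`` appends ``dafi``,
    ``n_assessed`` and ``category`` columns.
    """

    def __init__(
        self,
        schema: IndicatorSchema | None = None,
        min_assessed: int = MIN_ASSESSED_DEFAULT,
    ):
        self.schema = schema
        self.min_assessed = min_assessed

    def fit(self, X: pd.DataFrame, y=None) -> "FrailtyIndex":
        schema = self.schema or IndicatorSchema()
        missing = [lab for lab in schema.labels if lab not in X.columns]
        if missing:
            raise ValidationError(
                f"indicator table is missing columns: {', '.join(missing[:5])}"
                + (" ..." if len(missing) > 5 else "")
            )
        self.schema_ = schema
        self.columns_ = [lab for lab in schema.labels if lab not in schema.excluded]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "schema_"):
            self.fit(X)
        vals = X[self.columns_].to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValidationError("indicator values must be 0, 1, 2 or missing")
        assessed = (~np.isnan(vals)).sum(axis=1)
        total = np.nansum(vals, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            score = total / (2.0 * assessed)
        valid = assessed >= self.min_assessed
        score = np.where(valid, score, np.nan)
        category = np.where(
            valid,
            np.select(
                [score < ROBUST_CUT, score < FRAIL_CUT], ["robust", "pre_frail"], "frail"
            ),
            "invalid",
        )
        out = X.drop(columns=self.columns_).copy()
        out["dafi"] = score
        out["n_assessed"] = assessed
        out["category"] = category
        return out
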