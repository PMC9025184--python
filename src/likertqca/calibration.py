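"""Fuzzy-set calibration of raw survey variables.

Construct sums are mapped to memberships in [0, 1] with a piecewise-linear
function anchored at three percentiles of the retained sample: full
non-membership at the 10th percentile, the crossover (0.5) at the median,
and full membership at the 90th percentile:

    m(x) = 0                                   x <= q10
         = (x - q10) / (2 (q50 - q10))         q10 < x <= q50
         = 0.5 + (x - q50) / (2 (q90 - q50))   q50 < x <= q90
         = 1                                   x > q90

Gender and age are calibrated directly (male 0 / female 1; ages 15/16/17 ->
0 / 0.5 / 1), and the 7-category use outcome through a fixed map
{1 -> 0, 2 -> 0.2, 3 -> 0.8, 4 -> 0.9, >=5 -> 1}.  Negation is 1 - m.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import studydesign as sd
from .scales import ConstructScores

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised for degenerate anchors or unrecognized category codes."""


@dataclass
class CalibrationThresholds:
    """Per-construct (q10, q50, q90) anchors on the raw score scale."""

    anchors: dict[str, tuple[float, float, float]]

    def __getitem__(self, construct: str) -> tuple[float, float, float]:
        return self.anchors[construct]

    def require_strict(self, construct: str) -> tuple[float, float, float]:
        q10, q50, q90 = self.anchors[construct]
        if not (q10 < q50 < q90):
            raise CalibrationError(
                f"{construct}: degenerate calibration anchors ({q10}, {q50}, {q90}); "
                "the piecewise calibration needs strictly increasing percentiles"
            )
        return q10, q50, q90

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({k: list(v) for k, v in self.anchors.items()},
                       indent=2, sort_keys=True)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationThresholds":
        data = json.loads(Path(path).read_text())
        return cls({k: tuple(float(x) for x in v) for k, v in data.items()})


def percentile_thresholds(
    scores: pd.DataFrame | pd.Series,
    percentiles: tuple[float, float, float] = (10.0, 50.0, 90.0),
) -> CalibrationThresholds:
    """Empirical anchors from the retained sample.

    Percentiles use linear interpolation between order statistics (the
    default estimator in the major statistics environments).  Anchors that
    collapse (q10 == q50 or q50 == q90) raise a degenerate-calibration error
    naming the construct.
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_frame(scores.name or "score")
    anchors: dict[str, tuple[float, float, float]] = {}
    for name in scores.columns:
        vals = scores[name].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            raise CalibrationError(f"{name}: no observations to calibrate from")
        q10, q50, q90 = np.percentile(vals, percentiles)
        if q10 == q50 or q50 == q90:
            raise CalibrationError(
                f"{name}: degenerate calibration anchors ({q10}, {q50}, {q90})"
            )
        anchors[name] = (float(q10), float(q50), float(q90))
    return CalibrationThresholds(anchors)


def calibrate(x, thresholds: tuple[float, float, float]):
    """Piecewise-linear membership of raw score(s) ``x`` given strict anchors.

    Continuous and nondecreasing; exactly 0 at q10, 0.5 at q50, 1 at q90.
    Accepts scalars or arrays.
    """
    q10, q50, q90 = thresholds
    if not (q10 < q50 < q90):
        raise CalibrationError(
            f"degenerate calibration anchors ({q10}, {q50}, {q90})"
        )
    arr = np.asarray(x, dtype=float)
    m = np.empty_like(arr)
    m = np.where(arr <= q10, 0.0,
        np.where(arr <= q50, (arr - q10) / (2.0 * (q50 - q10)),
        np.where(arr <= q90, 0.5 + (arr - q50) / (2.0 * (q90 - q50)), 1.0)))
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(m)
    return m


def calibrate_gender(code):
    """0 for males, 1 for females."""
    arr = np.asarray(code, dtype=float)
    if not np.all(np.isin(arr[~np.isnan(arr)], (0.0, 1.0))):
        raise CalibrationError("gender codes must be 0 (male) or 1 (female)")
    return float(arr) if np.ndim(code) == 0 else arr


def calibrate_age(code):
    """Ages 15 / 16 / 17 -> memberships 0 / 0.5 / 1."""
    arr = np.asarray(code, dtype=float)
    if not np.all(np.isin(arr[~np.isnan(arr)], (15.0, 16.0, 17.0))):
        raise CalibrationError("age codes must be 15, 16 or 17")
    m = (arr - 15.0) / 2.0
    return float(m) if np.ndim(code) == 0 else m


def calibrate_use(y, outcome_map: dict[int, float] | None = None):
    """Outcome membership of use category ``y`` in 1..7."""
    mapping = outcome_map or sd.DEFAULT_OUTCOME_MAP
    arr = np.asarray(y)
    flat = np.atleast_1d(arr)
    out = np.empty(flat.shape, dtype=float)
    for i, v in enumerate(flat):
        iv = int(v)
        if iv != v or iv not in mapping:
            raise CalibrationError(f"outcome category {v!r} outside 1..7")
        out[i] = mapping[iv]
    if np.ndim(y) == 0:
        return float(out[0])
    return out.reshape(arr.shape)


def negate(m):
    """Fuzzy negation 1 - m (an involution on [0, 1])."""
    arr = np.asarray(m, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise CalibrationError("memberships must lie in [0, 1]")
    out = 1.0 - arr
    return float(out) if np.ndim(m) == 0 else out


@dataclass
class FuzzyDataset:
    """Calibrated memberships for the retained respondents.

    ``memberships`` holds one column per condition (GENDER, AGE and the five
    constructs); ``outcome_membership`` is the use-set membership.
    """

    memberships: pd.DataFrame
    outcome_membership: pd.Series
    thresholds: CalibrationThresholds | None = None
    epsilon_adjusted: int = 0

    @property
    def conditions(self) -> list[str]:
        return list(self.memberships.columns)

    @property
    def n_cases(self) -> int:
        return len(self.memberships)


def calibrate_dataset(
    scores: ConstructScores,
    thresholds: CalibrationThresholds | None = None,
    percentiles: tuple[float, float, float] = (10.0, 50.0, 90.0),
    outcome_map: dict[int, float] | None = None,
    crossover_epsilon: float = 0.0,
) -> FuzzyDataset:
    """Calibrate an entire retained sample to a :class:`FuzzyDataset`.

    ``thresholds`` may inject published anchors; otherwise anchors are the
    empirical percentiles of the retained scores.  ``crossover_epsilon`` > 0
    nudges condition memberships sitting exactly at 0.5 up by that amount
    (never the outcome membership): cases at the crossover are maximally
    ambiguous for truth-table assignment and would otherwise be dropped
    there.  The number of adjusted entries is logged and recorded.
    """
    if thresholds is None:
        thresholds = percentile_thresholds(scores.scores, percentiles)
    cols: dict[str, np.ndarray] = {
        sd.GENDER: calibrate_gender(scores.gender.to_numpy()),
        sd.AGE: calibrate_age(scores.age.to_numpy()),
    }
    for name in scores.scores.columns:
        cols[name] = calibrate(
            scores.scores[name].to_numpy(), thresholds.require_strict(name)
        )
    order = [c for c in sd.CONDITIONS if c in cols] + [
        c for c in cols if c not in sd.CONDITIONS
    ]
    memberships = pd.DataFrame({c: cols[c] for c in order}, index=scores.retained_ids)

    adjusted = 0
    if crossover_epsilon > 0:
        at_crossover = memberships == 0.5
        adjusted = int(at_crossover.to_numpy().sum())
        memberships = memberships.where(~at_crossover, 0.5 + crossover_epsilon)
        if adjusted:
            logger.info(
                "crossover epsilon %.4g applied to %d condition memberships at 0.5",
                crossover_epsilon, adjusted,
            )

    outcome_m = pd.Series(
        calibrate_use(scores.outcome.to_numpy(), outcome_map),
        index=scores.retained_ids, name="m_USE",
    )
    return FuzzyDataset(memberships, outcome_m, thresholds, adjusted)
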