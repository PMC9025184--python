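"""Scale reliability and construct scoring.

Multi-item constructs are validated with Cronbach's alpha and aggregated to
simple item sums.  Respondents with any missing value on an analysed item,
on gender/age, or on the outcome are removed once, globally (listwise
deletion), and every downstream stage works on that same retained sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import studydesign as sd
from .synthetic import SurveyDataset


class ScaleError(ValueError):
    """Raised for undefined reliability or unknown items."""


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Cronbach's alpha of one construct's respondent-by-item table.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the item sum),
    with sample (n-1) variances, computed on complete cases only.
    """
    if items.shape[1] < 2:
        raise ScaleError("Cronbach's alpha requires at least 2 items")
    complete = items.dropna()
    if len(complete) < 3:
        raise ScaleError("Cronbach's alpha requires at least 3 complete respondents")
    values = complete.to_numpy(dtype=float)
    k = values.shape[1]
    item_vars = values.var(axis=0, ddof=1)
    total_var = values.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ScaleError("total score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


@dataclass
class ConstructScores:
    """Item sums for the retained (listwise-complete) respondents.

    ``scores`` has one column per construct; ``gender``, ``age`` and
    ``outcome`` are aligned on the same retained index.
    """

    scores: pd.DataFrame
    gender: pd.Series
    age: pd.Series
    outcome: pd.Series
    score_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_total: int = 0

    @property
    def retained_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def n_retained(self) -> int:
        return len(self.scores)

    @property
    def n_dropped(self) -> int:
        return self.n_total - self.n_retained


def sum_scores(
    dataset: SurveyDataset, construct_map: dict[str, list[str]] | None = None
) -> ConstructScores:
    """Aggregate items to construct sums with global listwise deletion.

    A respondent is retained only if every mapped item, gender, age and the
    outcome are observed; sums are taken on the raw Likert codes.
    """
    cmap = construct_map or dataset.construct_map
    df = dataset.responses
    for name, items in cmap.items():
        unknown = [c for c in items if c not in df.columns]
        if unknown:
            raise ScaleError(f"{name}: unknown items {unknown}")
    for col in (sd.GENDER, sd.AGE, sd.OUTCOME):
        if col not in df.columns:
            raise ScaleError(f"dataset lacks required column {col}")

    analysed = [c for items in cmap.values() for c in items]
    analysed += [sd.GENDER, sd.AGE, sd.OUTCOME]
    retained = df[analysed].dropna()

    scores = pd.DataFrame(
        {name: retained[items].sum(axis=1) for name, items in cmap.items()}
    )
    ranges = {
        name: (len(items) * _likert_min(name), len(items) * _likert_max(name))
        for name, items in cmap.items()
    }
    return ConstructScores(
        scores=scores,
        gender=retained[sd.GENDER],
        age=retained[sd.AGE],
        outcome=retained[sd.OUTCOME],
        score_ranges=ranges,
        n_total=len(df),
    )


def _likert_min(name: str) -> int:
    return sd.CONSTRUCT_DESIGN[name][1] if name in sd.CONSTRUCT_DESIGN else 1


def _likert_max(name: str) -> int:
    return sd.CONSTRUCT_DESIGN[name][2] if name in sd.CONSTRUCT_DESIGN else 5


def reliability_report(
    dataset: SurveyDataset, construct_map: dict[str, list[str]] | None = None
) -> pd.Series:
    """Cronbach's alpha per construct (complete cases per construct)."""
    cmap = construct_map or dataset.construct_map
    return pd.Series(
        {name: cronbach_alpha(dataset.responses[items]) for name, items in cmap.items()},
        name="cronbach_alpha",
    )
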