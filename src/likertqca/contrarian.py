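"""Contrarian-case screening ahead of configurational analysis.

Each calibrated condition is cross-tabulated against the outcome after
quintile binning, and association is summarized with the Phi coefficient
(sqrt(chi-square / n)) and Kendall's tau-b.  A condition with Phi^2 < 0.5
leaves enough cases off the main diagonal — contrarian cases — that a
configurational (set-theoretic) analysis is warranted in addition to the
regression.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import studydesign as sd
from .calibration import FuzzyDataset

logger = logging.getLogger(__name__)

PHI_SQUARED_RULE = 0.5


class AssociationError(ValueError):
    """Raised for degenerate crosstabs or all-tied vectors."""


def quintile_bins(values) -> np.ndarray:
    """Bin a vector at its 20/40/60/80 percentiles into labels 1..5.

    Heavily tied inputs can collapse bin edges; collapsed bins are dropped
    and labels renumbered consecutively (logged), so fewer than five
    nonempty bins may result.  A constant vector yields a single bin.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise AssociationError("cannot bin an empty vector")
    edges = np.percentile(arr, [20, 40, 60, 80])
    unique_edges = np.unique(edges)
    if unique_edges.size < edges.size:
        logger.info("quintile bin edges collapsed: %s -> %s", edges, unique_edges)
    # Right-closed bins: value <= edge stays in the lower bin.
    labels = 1 + np.searchsorted(unique_edges, arr, side="left")
    # Renumber so labels are consecutive starting at 1.
    present = np.unique(labels)
    remap = np.zeros(present.max() + 1, dtype=int)
    remap[present] = np.arange(1, present.size + 1)
    return remap[labels]


def phi_statistic(crosstab: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Phi = sqrt(chi2 / n) with the Pearson chi-square (no continuity
    correction); the p-value uses (r-1)(c-1) degrees of freedom.

    For tables larger than 2x2 this generalization can exceed 1.
    """
    table = np.asarray(crosstab, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise AssociationError("crosstab must be a nonnegative 2-D count table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise AssociationError("crosstab has a zero margin")
    n = table.sum()
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(np.sqrt(chi2 / n)), float(p)


def cramers_v(crosstab: pd.DataFrame | np.ndarray) -> float:
    """Cramér's V, offered alongside Phi for tables larger than 2x2."""
    table = np.asarray(crosstab, dtype=float)
    phi, _ = phi_statistic(table)
    k = min(table.shape) - 1
    if k < 1:
        raise AssociationError("crosstab needs at least 2 rows and 2 columns")
    return float(phi / np.sqrt(k))


def kendall_tau_b(x, y) -> tuple[float, float]:
    """Kendall's tau-b with tie correction and a normal-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise AssociationError("tau-b needs two equal-length vectors of size >= 2")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise AssociationError("tau-b undefined for an all-tied vector")
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic), float(res.pvalue)


@dataclass
class AssociationStats:
    """Association of one condition with the outcome."""

    condition: str
    phi: float
    phi_p_value: float
    tau_b: float
    tau_p_value: float
    crosstab: pd.DataFrame
    cramers_v: float
    configurational_justified: bool = False

    @property
    def phi_squared(self) -> float:
        return self.phi ** 2


@dataclass
class ScreenReport:
    """Per-condition association statistics plus the Phi^2 < 0.5 screen."""

    stats: list[AssociationStats] = field(default_factory=list)
    n_cases: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phi": [s.phi for s in self.stats],
                "phi_p": [s.phi_p_value for s in self.stats],
                "phi_squared": [s.phi_squared for s in self.stats],
                "tau_b": [s.tau_b for s in self.stats],
                "tau_p": [s.tau_p_value for s in self.stats],
                "cramers_v": [s.cramers_v for s in self.stats],
                "configurational_justified": [
                    s.configurational_justified for s in self.stats
                ],
            },
            index=pd.Index([s.condition for s in self.stats], name="condition"),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_cases": self.n_cases,
            "phi_squared_rule": PHI_SQUARED_RULE,
            "conditions": {
                s.condition: {
                    "phi": s.phi,
                    "phi_p_value": s.phi_p_value,
                    "phi_squared": s.phi_squared,
                    "tau_b": s.tau_b,
                    "tau_p_value": s.tau_p_value,
                    "cramers_v": s.cramers_v,
                    "configurational_justified": s.configurational_justified,
                }
                for s in self.stats
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def association_stats(
    condition: str, membership, outcome_codes, bin_outcome: bool = True
) -> AssociationStats:
    """Quintile crosstab + Phi + tau-b of one calibrated condition against
    the raw outcome codes (1..7)."""
    m = np.asarray(membership, dtype=float)
    y = np.asarray(outcome_codes, dtype=float)
    x_bins = quintile_bins(m)
    y_bins = quintile_bins(y) if bin_outcome else y.astype(int)
    table = pd.crosstab(pd.Series(x_bins, name=condition), pd.Series(y_bins, name=sd.OUTCOME))
    phi, phi_p = phi_statistic(table)
    tau, tau_p = kendall_tau_b(m, y)
    return AssociationStats(
        condition=condition,
        phi=phi,
        phi_p_value=phi_p,
        tau_b=tau,
        tau_p_value=tau_p,
        crosstab=table,
        cramers_v=cramers_v(table),
    )


def contrarian_screen(
    fuzzy: FuzzyDataset, outcome_codes, bin_outcome: bool = True
) -> ScreenReport:
    """Screen every condition; Phi^2 strictly below 0.5 flags that enough
    contrarian cases exist to justify the configurational analysis."""
    report = ScreenReport(n_cases=fuzzy.n_cases)
    for cond in fuzzy.conditions:
        s = association_stats(
            cond, fuzzy.memberships[cond].to_numpy(), outcome_codes, bin_outcome
        )
        s.configurational_justified = s.phi_squared < PHI_SQUARED_RULE
        report.stats.append(s)
    return report
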