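"""Proportional-odds ordered logistic regression of the use outcome.

The model is the cumulative-logit form P(y <= j | x) = expit(kappa_j - x'b)
with one coefficient vector shared across all J-1 cutpoints, fitted by
maximum likelihood.  Reported alongside the coefficients: odds ratios,
z-ratios with two-sided normal p-values, 95% CIs on the OR scale, the
likelihood-ratio test against the cutpoints-only null, and McFadden's
pseudo-R^2 (1 - loglik / loglik_null, with the cutpoints-only null).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # normal 97.5% quantile


class FitError(RuntimeError):
    """Raised when the likelihood maximization fails to converge."""


@dataclass
class OLRFit:
    predictors: list[str]
    coefficients: np.ndarray  # log-odds scale
    std_errors: np.ndarray
    cutpoints: np.ndarray  # J-1 increasing
    loglik: float
    loglik_null: float
    n_used: int
    n_categories: int
    collapsed_categories: list[int]
    unstable_se: bool = False

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def z_scores(self) -> np.ndarray:
        return self.coefficients / self.std_errors

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z_scores))

    @property
    def ci95(self) -> np.ndarray:
        """(low, high) per predictor on the OR scale."""
        lo = np.exp(self.coefficients - Z_95 * self.std_errors)
        hi = np.exp(self.coefficients + Z_95 * self.std_errors)
        return np.column_stack([lo, hi])

    @property
    def lr_statistic(self) -> float:
        return 2.0 * (self.loglik - self.loglik_null)

    @property
    def lr_p(self) -> float:
        df = len(self.predictors)
        if df == 0:
            return 1.0
        return float(stats.chi2.sf(self.lr_statistic, df))

    @property
    def pseudo_r2(self) -> float:
        """McFadden's pseudo-R^2 against the cutpoints-only null."""
        if self.loglik_null == 0.0:
            return 0.0
        return 1.0 - self.loglik / self.loglik_null


def _null_loglik(y: np.ndarray) -> float:
    """Log-likelihood of the cutpoints-only model, whose MLE reproduces the
    empirical category frequencies."""
    _, counts = np.unique(y, return_counts=True)
    n = counts.sum()
    return float(np.sum(counts * np.log(counts / n)))


def fit_olr(X: pd.DataFrame | None, y, maxiter: int = 500) -> OLRFit:
    """Fit the proportional-odds model by maximum likelihood.

    Empty outcome categories are collapsed with a logged warning (the
    likelihood does not depend on them).  Non-convergence raises
    :class:`FitError`; suspiciously large estimates or standard errors
    (complete separation) set ``unstable_se`` and emit a warning.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y != np.round(y)):
        raise ValueError("outcome categories must be integers")
    observed = np.unique(y)
    if observed.size < 2:
        raise ValueError("outcome must take at least two distinct categories")
    all_cats = np.arange(y.min(), y.max() + 1)
    collapsed = [int(c) for c in all_cats if c not in observed]
    if collapsed:
        logger.warning("collapsing empty outcome categories: %s", collapsed)
    # Re-code to consecutive ranks 0..J-1 over observed categories.
    rank = {c: i for i, c in enumerate(observed)}
    y_ranked = np.array([rank[v] for v in y])
    ll0 = _null_loglik(y_ranked)

    if X is None or X.shape[1] == 0:
        # Cutpoints-only model: closed form via empirical cumulative logits.
        _, counts = np.unique(y_ranked, return_counts=True)
        cum = np.cumsum(counts)[:-1] / counts.sum()
        cutpoints = np.log(cum / (1.0 - cum))
        return OLRFit(
            predictors=[], coefficients=np.empty(0), std_errors=np.empty(0),
            cutpoints=cutpoints, loglik=ll0, loglik_null=ll0,
            n_used=y.size, n_categories=observed.size,
            collapsed_categories=collapsed,
        )

    if isinstance(X, np.ndarray):
        X = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    if len(X) != y.size:
        raise ValueError("X and y lengths differ")
    if np.any(X.std(axis=0).to_numpy() == 0):
        raise ValueError("constant predictor column; drop it before fitting")

    model = OrderedModel(y_ranked, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=maxiter, disp=False)
    if not res.mle_retvals.get("converged", False):
        raise FitError(
            "ordered-logit likelihood maximization did not converge: "
            f"{res.mle_retvals}"
        )
    k = X.shape[1]
    coefs = np.asarray(res.params[:k], dtype=float)
    ses = np.asarray(res.bse[:k], dtype=float)
    cutpoints = np.asarray(model.transform_threshold_params(res.params)[1:-1], dtype=float)

    unstable = bool(np.any(np.abs(coefs) > 20) or np.any(ses > 100) or np.any(~np.isfinite(ses)))
    if unstable:
        logger.warning(
            "possible complete separation: extreme coefficients or standard "
            "errors; inference is unstable"
        )
    return OLRFit(
        predictors=list(X.columns),
        coefficients=coefs,
        std_errors=ses,
        cutpoints=cutpoints,
        loglik=float(res.llf),
        loglik_null=ll0,
        n_used=y.size,
        n_categories=observed.size,
        collapsed_categories=collapsed,
        unstable_se=unstable,
    )


def olr_report(fit: OLRFit) -> pd.DataFrame:
    """One row per predictor: OR, log-OR, SE, z, p, 95% CI (OR scale)."""
    ci = fit.ci95
    return pd.DataFrame(
        {
            "OR": fit.odds_ratios,
            "log_OR": fit.coefficients,
            "std_error": fit.std_errors,
            "z_ratio": fit.z_scores,
            "p_value": fit.p_values,
            "ci95_low": ci[:, 0] if len(fit.predictors) else np.empty(0),
            "ci95_high": ci[:, 1] if len(fit.predictors) else np.empty(0),
        },
        index=pd.Index(fit.predictors, name="predictor"),
    )


def olr_report_json(fit: OLRFit, path: str | Path | None = None) -> str:
    frame = olr_report(fit)
    payload = {
        "predictors": {
            name: {k: float(v) for k, v in row.items()}
            for name, row in frame.iterrows()
        },
        "cutpoints": [float(c) for c in fit.cutpoints],
        "loglik": fit.loglik,
        "loglik_null": fit.loglik_null,
        "lr_statistic": fit.lr_statistic,
        "lr_p": fit.lr_p,
        "pseudo_r2": fit.pseudo_r2,
        "n_used": fit.n_used,
        "collapsed_categories": fit.collapsed_categories,
        "unstable_se": fit.unstable_se,
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def olr_report_text(fit: OLRFit) -> str:
    """Aligned text table with the LR and pseudo-R^2 footer."""
    frame = olr_report(fit)
    lines = [
        f"{'Predictor':<10} {'OR':>9} {'log OR':>9} {'SE':>8} "
        f"{'z':>8} {'p':>9} {'95% CI (OR)':>18}"
    ]
    for name, row in frame.iterrows():
        ci = f"[{row.ci95_low:.3f}, {row.ci95_high:.3f}]"
        lines.append(
            f"{name:<10} {row.OR:>9.3f} {row.log_OR:>9.3f} {row.std_error:>8.3f} "
            f"{row.z_ratio:>8.3f} {row.p_value:>9.4f} {ci:>18}"
        )
    lines.append(f"LR ratio = {fit.lr_statistic:.2f} (p = {fit.lr_p:.4g})")
    lines.append(f"McFadden pseudo R^2 = {100 * fit.pseudo_r2:.2f}%")
    return "\n".join(lines)
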