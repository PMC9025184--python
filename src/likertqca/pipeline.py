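"""End-to-end study pipeline.

Stages run in a fixed order: load or generate the survey; listwise
deletion; scale reliability; construct scores; calibration anchors; fuzzy
calibration; contrarian-case screen; ordered logistic regression; fsQCA for
use and non-use; report assembly.  Every stage failure is re-raised with a
stage label, and the whole run is reproducible bit-for-bit given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import studydesign as sd
from . import qca
from .calibration import (CalibrationThresholds, FuzzyDataset, calibrate_dataset)
from .config import StudyConfig
from .contrarian import ScreenReport, contrarian_screen
from .ordered_logit import OLRFit, fit_olr, olr_report, olr_report_text
from .scales import ConstructScores, reliability_report, sum_scores
from .synthetic import SurveyDataset, generate_survey

logger = logging.getLogger(__name__)

STAGES = (
    "load", "scores", "alphas", "thresholds", "calibration",
    "contrarian", "olr", "qca_use", "qca_nonuse", "report",
)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class StudyReport:
    config: StudyConfig
    dataset: SurveyDataset
    scores: ConstructScores
    alphas: pd.Series
    thresholds: CalibrationThresholds
    fuzzy: FuzzyDataset
    screen: ScreenReport
    olr: OLRFit
    use_analysis: qca.OutcomeAnalysis
    nonuse_analysis: qca.OutcomeAnalysis
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_respondents": self.dataset.n_respondents,
            "n_retained": self.scores.n_retained,
            "n_dropped": self.scores.n_dropped,
            "cronbach_alpha": {k: float(v) for k, v in self.alphas.items()},
            "calibration_thresholds": {
                k: list(v) for k, v in self.thresholds.anchors.items()
            },
            "crossover_epsilon_adjusted": self.fuzzy.epsilon_adjusted,
            "contrarian_screen": json.loads(self.screen.to_json()),
            "ordered_logit": {
                "table": {
                    name: {k: float(v) for k, v in row.items()}
                    for name, row in olr_report(self.olr).iterrows()
                },
                "cutpoints": [float(c) for c in self.olr.cutpoints],
                "loglik": self.olr.loglik,
                "loglik_null": self.olr.loglik_null,
                "lr_statistic": self.olr.lr_statistic,
                "lr_p": self.olr.lr_p,
                "pseudo_r2": self.olr.pseudo_r2,
                "n_used": self.olr.n_used,
            },
            "fsqca": json.loads(
                qca.analysis_to_json([self.use_analysis, self.nonuse_analysis])
            ),
            "warnings": list(self.warnings),
            "seed": self.config.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def tables_text(self) -> str:
        """Human-readable report: reliability/association table, the
        ordered-logit table, and the solution matrices for use and
        non-use."""
        parts: list[str] = []
        screen_frame = self.screen.to_frame()
        assoc = pd.DataFrame(
            {
                "alpha": self.alphas.reindex(screen_frame.index),
                "phi": screen_frame["phi"],
                "phi_p": screen_frame["phi_p"],
                "tau_b": screen_frame["tau_b"],
                "tau_p": screen_frame["tau_p"],
            }
        )
        anchor_cols = pd.DataFrame(
            {
                "q10": {k: v[0] for k, v in self.thresholds.anchors.items()},
                "q50": {k: v[1] for k, v in self.thresholds.anchors.items()},
                "q90": {k: v[2] for k, v in self.thresholds.anchors.items()},
            }
        )
        assoc = assoc.join(anchor_cols)
        parts.append("== Scale reliability, association screen, calibration anchors ==")
        parts.append(assoc.to_string(float_format=lambda v: f"{v:.3f}"))
        parts.append("")
        parts.append("== Ordered logistic regression ==")
        parts.append(olr_report_text(self.olr))
        parts.append("")
        parts.append("== fsQCA solutions ==")
        for analysis in (self.use_analysis, self.nonuse_analysis):
            for sol in (analysis.complex, analysis.parsimonious, analysis.intermediate):
                parts.append(qca.solution_matrix_text(sol))
                parts.append("")
            parts.append(
                f"{analysis.outcome_label}: core conditions = "
                f"{', '.join(analysis.core_conditions) or 'none'}; "
                f"peripheral = {', '.join(analysis.peripheral_conditions) or 'none'}"
            )
            parts.append("")
        return "\n".join(parts)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json())
        (outdir / "tables.txt").write_text(self.tables_text())
        (outdir / "log.txt").write_text("\n".join(self.warnings) + "\n")


class _ListHandler(logging.Handler):
    def __init__(self, sink: list[str]):
        super().__init__(level=logging.INFO)
        self.sink = sink

    def emit(self, record: logging.LogRecord) -> None:
        self.sink.append(f"{record.levelname.lower()}: {record.getMessage()}")


def run_pipeline(
    config: StudyConfig, dataset: SurveyDataset | None = None
) -> StudyReport:
    """Execute the full study on a provided or generated survey."""
    config.validate()
    warnings_log: list[str] = []
    handler = _ListHandler(warnings_log)
    root = logging.getLogger("likertqca")
    root.addHandler(handler)
    try:
        return _run(config, dataset, warnings_log)
    finally:
        root.removeHandler(handler)


def _run(config: StudyConfig, dataset, warnings_log) -> StudyReport:
    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    if dataset is None:
        if config.data_path is not None:
            dataset = stage("load", SurveyDataset.from_csv,
                            config.data_path, config.construct_map)
        else:
            gen = config.generator
            if gen.seed is None and config.seed is not None:
                gen = replace(gen, seed=config.seed)
            dataset = stage("load", generate_survey, gen)

    scores = stage("scores", sum_scores, dataset, config.construct_map)
    alphas = stage("alphas", reliability_report, dataset, config.construct_map)

    if config.thresholds is not None:
        thresholds = CalibrationThresholds(
            {k: tuple(v) for k, v in config.thresholds.items()}
        )
    else:
        thresholds = None
    fuzzy = stage(
        "calibration", calibrate_dataset, scores,
        thresholds=thresholds,
        percentiles=config.calibration_percentiles,
        outcome_map=config.outcome_map,
        crossover_epsilon=config.crossover_epsilon,
    )

    screen = stage("contrarian", contrarian_screen, fuzzy,
                   scores.outcome.to_numpy(), config.bin_outcome)
    olr = stage("olr", fit_olr, fuzzy.memberships, scores.outcome.to_numpy())

    use_analysis = stage(
        "qca_use", qca.analyze_outcome, fuzzy.memberships,
        fuzzy.outcome_membership.to_numpy(), "USE", config.expectations,
        config.frequency_cutoff, config.consistency_cutoff,
    )
    nonuse_analysis = stage(
        "qca_nonuse", qca.analyze_outcome, fuzzy.memberships,
        fuzzy.outcome_membership.to_numpy(), "~USE", config.expectations,
        config.frequency_cutoff, config.consistency_cutoff,
    )

    return StudyReport(
        config=config,
        dataset=dataset,
        scores=scores,
        alphas=alphas,
        thresholds=fuzzy.thresholds,
        fuzzy=fuzzy,
        screen=screen,
        olr=olr,
        use_analysis=use_analysis,
        nonuse_analysis=nonuse_analysis,
        warnings=warnings_log,
    )
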