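"""End-to-end orchestration: simulate → label → stage → adherence →
transitions → train.

The pipeline mirrors a retrospective-cohort workflow: build (or load) a
patient-year table with notes, filter to patients with an HbA1c value
in every study year and complete predictors, derive structured labels
from the notes, assign stages, cross-tabulate prescribing concordance,
estimate 1- and 2-year transition matrices, and fit the twelve nested
transition-prediction tasks. Every stochastic stage receives the single
configured seed, so a rerun with the same config reproduces the report
bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import adherence as adh
from . import cohort as cohort_mod
from . import models as models_mod
from . import nlp
from . import staging
from .cohort import CohortConfig
from .models import TrainConfig

logger = logging.getLogger("dmtransit")

PREDICTOR_COLUMNS = [
    "age",
    "ldl_cholesterol",
    "egfr",
    "creatinine",
    "bmi",
    "weight",
    "height",
    "diastolic_bp",
    "systolic_bp",
]


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    lexicon_path: str | None = None
    horizons: tuple[int, ...] = (1, 2)
    train: TrainConfig | None = None
    output_dir: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PipelineConfig":
        payload = dict(payload)
        if "cohort" in payload and isinstance(payload["cohort"], Mapping):
            payload["cohort"] = CohortConfig.from_dict(payload["cohort"])
        if "train" in payload and isinstance(payload["train"], Mapping):
            train = dict(payload["train"])
            if train.pop("fast", True):
                payload["train"] = TrainConfig.fast(
                    seed=train.get("seed", 0), resampling=train.get("resampling", "none")
                )
            else:
                payload["train"] = TrainConfig(**train)
        if "horizons" in payload:
            payload["horizons"] = tuple(payload["horizons"])
        return cls(**payload)


def filter_cohort(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Inclusion filter: HbA1c in every study year, complete predictors.

    Mirrors the funnel of a fixed three-year panel: patients missing an
    HbA1c measurement in any study year are removed first, then patients
    with any missing modeled predictor (no imputation). Returns the
    filtered table and per-rule removal counts.
    """
    n_years = records["year"].nunique()
    counts: dict[str, int] = {"initial_patients": records["patient_id"].nunique()}
    have_hba1c = records.groupby("patient_id")["hba1c"].apply(
        lambda s: s.notna().all() and len(s) == n_years
    )
    keep_ids = have_hba1c[have_hba1c].index
    counts["removed_missing_hba1c"] = counts["initial_patients"] - len(keep_ids)
    filtered = records[records["patient_id"].isin(keep_ids)]
    present = [c for c in PREDICTOR_COLUMNS if c in filtered.columns]
    complete = filtered.groupby("patient_id")[present].apply(
        lambda g: g.notna().all().all()
    )
    keep_ids2 = complete[complete].index
    counts["removed_missing_predictor"] = len(keep_ids) - len(keep_ids2)
    filtered = filtered[filtered["patient_id"].isin(keep_ids2)]
    counts["included_patients"] = filtered["patient_id"].nunique()
    logger.info("inclusion filter: %s", counts)
    return filtered.reset_index(drop=True), counts


def label_cohort(
    records: pd.DataFrame,
    lexicon: nlp.Lexicon | None = None,
    patterns: nlp.AdherencePatterns | None = None,
) -> tuple[pd.DataFrame, dict]:
    """NLP-label every note and backfill the structured fields.

    Returns the completed table (adds ``drugs``, ``conditions``,
    ``adherence``, recommendation flags and professional
    guideline-adherence flags) and the per-row extraction results keyed
    by ``(patient_id, year)`` for auditing and evaluation.
    """
    lexicon = lexicon or nlp.default_lexicon()
    rows, results = [], {}
    for record in records.to_dict(orient="records"):
        extraction = nlp.extract_record(record.get("note_text", "") or "", lexicon, patterns)
        results[(record["patient_id"], record["year"])] = extraction
        merged = nlp.merge_structured(record, extraction)
        merged["drugs"] = merged.pop("drugs_structured")
        merged["conditions"] = merged.pop("conditions_structured", "")
        for cat in nlp.RECOMMENDATION_CATEGORIES:
            col = cat.replace("recommendation_", "rec_")
            merged[col] = bool(merged.get(col, False))
        merged["guideline_markers"] = sorted(extraction.guideline_markers)
        if pd.notna(merged.get("hba1c")) and pd.notna(merged.get("egfr")):
            flags = adh.professional_adherence_flags(merged)
        else:
            flags = {"hba1c_guide": False, "cholesterol_guide": False}
        merged.update(flags)
        merged.pop("_provenance", None)
        merged.pop("_conflicts", None)
        rows.append(merged)
    labeled = pd.DataFrame(rows)
    logger.info("labeled %d patient-years", len(labeled))
    return labeled, results


def adherence_cross_tabs(
    records: pd.DataFrame, labeled: pd.DataFrame
) -> dict[str, adh.AdherenceCrossTab]:
    """Ideal-vs-prescribed cross-tabs before and after NLP backfill.

    "Before" uses only the structured drug field; "after" uses the
    NLP-completed drug list. Patient-years untreated in *both* views are
    excluded so the two tables cover the same population.
    """
    def classes(frame: pd.DataFrame, column: str) -> pd.Series:
        drugs = frame[column].fillna("").map(lambda v: [d for d in str(v).split(";") if d])
        return drugs.map(adh.actual_treatment)

    before_actual = classes(records, "drugs_structured")
    after_actual = classes(labeled, "drugs")
    ideal = [
        adh.ideal_treatment(h, e) if pd.notna(h) and pd.notna(e) else None
        for h, e in zip(labeled["hba1c"], labeled["egfr"])
    ]
    mask = [
        i is not None and a != adh.TREATMENT_NONE
        for i, a in zip(ideal, after_actual)
    ]
    result = {}
    for name, actual in (("before_nlp", before_actual), ("after_nlp", after_actual)):
        pairs = [
            (i, a)
            for i, a, m in zip(ideal, actual, mask)
            if m and a != adh.TREATMENT_NONE
        ]
        result[name] = adh.cross_tab([p[0] for p in pairs], [p[1] for p in pairs])
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report dictionary.

    When ``config.output_dir`` is set, intermediate artifacts
    (cohort.csv, truth.jsonl, labeled.csv, staged.csv,
    transitions.json, model_metrics.json, report.json) are written
    there; partial artifacts are retained if a later stage fails.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    lexicon = (
        nlp.Lexicon.from_json(config.lexicon_path)
        if config.lexicon_path
        else nlp.default_lexicon()
    )

    records, truth = cohort_mod.generate_cohort(config.cohort, lexicon=lexicon)
    report: dict = {
        "seed": config.cohort.seed,
        "n_patients_generated": int(records["patient_id"].nunique()),
        "config": {"cohort_years": list(config.cohort.years)},
    }
    if out_dir:
        cohort_mod.write_cohort(records, out_dir / "cohort.csv")
        cohort_mod.write_truth(truth, out_dir / "truth.jsonl")
    if len(records) == 0:
        raise cohort_mod.GenerationError("staging requires a nonempty cohort")

    filtered, filter_counts = filter_cohort(records)
    report["inclusion_filter"] = filter_counts
    if len(filtered) == 0:
        raise cohort_mod.GenerationError(
            "staging requires a nonempty cohort after filtering"
        )

    labeled, extraction_results = label_cohort(filtered, lexicon)
    if out_dir:
        labeled.drop(columns=["note_text"]).to_csv(out_dir / "labeled.csv", index=False)
    kept = truth.merge(
        filtered[["patient_id", "year"]], on=["patient_id", "year"]
    )
    quality = nlp.evaluate_extraction(extraction_results, kept)
    report["extraction_quality"] = quality[["precision", "recall", "f1"]].round(4).to_dict(
        orient="index"
    )

    staged = staging.stage_cohort(labeled)
    if out_dir:
        staged.drop(columns=["note_text"]).to_csv(out_dir / "staged.csv", index=False)
    stage_counts = staged.groupby("stage")["patient_id"].count().to_dict()
    report["stage_counts"] = {k: int(v) for k, v in stage_counts.items()}

    tabs = adherence_cross_tabs(filtered, labeled)
    report["adherence_cross_tab"] = {
        name: {
            "counts": tab.counts.tolist(),
            "row_percentages": np.round(tab.row_percentages, 2).tolist(),
        }
        for name, tab in tabs.items()
    }

    matrices = staging.summarize_transitions(staged, horizons=config.horizons)
    report["transition_matrices"] = {
        str(h): m.to_dict() for h, m in matrices.items()
    }
    if out_dir:
        with open(out_dir / "transitions.json", "w", encoding="utf-8") as fh:
            json.dump(report["transition_matrices"], fh, indent=1)

    if config.train is not None:
        bundle = models_mod.fit_all_tasks(staged, config.train)
        report["model_metrics"] = {key: fit.summary() for key, fit in bundle.items()}
        report["n_fitted_tasks"] = len(bundle)
        if out_dir:
            with open(out_dir / "model_metrics.json", "w", encoding="utf-8") as fh:
                json.dump(report["model_metrics"], fh, indent=1, default=float)
            try:
                import joblib

                joblib.dump(
                    {"bundle": bundle, "seed": config.cohort.seed},
                    out_dir / "models.joblib",
                )
            except ImportError:
                pass

    if out_dir:
        with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, default=float)
        (out_dir / "report.md").write_text(render_report_markdown(report), encoding="utf-8")
    return report


def render_report_markdown(report: Mapping) -> str:
    lines = ["# Pipeline run report", ""]
    lines.append(f"Seed: {report['seed']}")
    lines.append(f"Patients generated: {report['n_patients_generated']}")
    if "inclusion_filter" in report:
        lines.append("")
        lines.append("## Inclusion filter")
        for key, value in report["inclusion_filter"].items():
            lines.append(f"- {key}: {value}")
    if "stage_counts" in report:
        lines.append("")
        lines.append("## Patient-years per stage")
        for key, value in sorted(report["stage_counts"].items()):
            lines.append(f"- {key}: {value}")
    if "transition_matrices" in report:
        lines.append("")
        lines.append("## Transition matrices (proportions)")
        for horizon, payload in report["transition_matrices"].items():
            lines.append(f"### {horizon}-year")
            for stage_name, row in zip(payload["stages"], payload["proportions"]):
                cells = ", ".join(f"{v:.4f}" for v in row)
                lines.append(f"- {stage_name}: {cells}")
    if "model_metrics" in report:
        lines.append("")
        lines.append("## Fitted transition models")
        for key, summary in report["model_metrics"].items():
            test = summary["test"]
            lines.append(
                f"- {key}: {summary['family']} "
                f"(test F1 {test['f1']:.3f}, AUC {test['auc']:.3f}, "
                f"cutoff {summary['cutoff']:.3f})"
            )
    return "\n".join(lines) + "\n"
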