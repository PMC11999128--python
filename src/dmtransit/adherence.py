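"""Guideline-adherence classification of hypoglycemic prescriptions.

Each patient-year is assigned an *actual* treatment class from the drug
list (insulin > combined > metformin > none, where "combined" means
metformin plus a second-line anti-diabetic) and an *ideal* class from a
configurable guideline band table over HbA1c and kidney function. The
cross-tabulation of ideal vs actual summarizes prescribing concordance;
its diagonal is the adherent mass. The shipped band table is an explicit
stand-in for the clinical-practice-guideline algorithm, not a transcription
of it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TREATMENT_CLASSES = ("metformin", "combined", "insulin")
TREATMENT_NONE = "none"
# Precedence order for NLP backfill monotonicity: adding drugs can only
# move a patient up this ladder.
TREATMENT_ORDER = (TREATMENT_NONE, "metformin", "combined", "insulin")


def load_drug_classes(path=None) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Canonical drug -> therapeutic class map plus combination products."""
    if path is None:
        ref = resources.files("dmtransit.data").joinpath("drug_classes.json")
        with ref.open(encoding="utf-8") as fh:
            payload = json.load(fh)
    else:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    return payload["classes"], payload["combinations"]


_CLASSES, _COMBINATIONS = load_drug_classes()


def expand_combinations(
    drugs: Iterable[str], combinations: Mapping[str, Sequence[str]] | None = None
) -> set[str]:
    """Expand combination products (``a+b``) into their components."""
    combos = _COMBINATIONS if combinations is None else combinations
    expanded: set[str] = set()
    for drug in drugs:
        if drug in combos:
            expanded.update(combos[drug])
        else:
            expanded.add(drug)
    return expanded


def drug_class(drug: str, classes: Mapping[str, str] | None = None) -> str:
    lookup = _CLASSES if classes is None else classes
    return lookup.get(drug, "other")


def actual_treatment(drugs: Iterable[str]) -> str:
    """Hypoglycemic treatment class actually prescribed.

    Any insulin dominates; metformin plus at least one second-line agent
    is "combined"; metformin alone is "metformin"; otherwise "none".
    Combination products are expanded first, so a single
    ``empagliflozin+metformin`` product classifies as combined.
    """
    expanded = expand_combinations(drugs)
    classes = {drug_class(d) for d in expanded}
    if "insulin" in classes:
        return "insulin"
    has_metformin = "hypoglycemic_first_line" in classes
    has_second = "hypoglycemic_second_line" in classes
    if has_metformin and has_second:
        return "combined"
    if has_metformin:
        return "metformin"
    return TREATMENT_NONE


@dataclass(frozen=True)
class GuidelineBand:
    """First-match band: condition over HbA1c / eGFR -> ideal class."""

    ideal: str
    hba1c_max: float = float("inf")  # band applies while hba1c < hba1c_max ...
    egfr_min: float = 0.0  # ... and egfr >= egfr_min

    def matches(self, hba1c: float, egfr: float) -> bool:
        return hba1c < self.hba1c_max and egfr >= self.egfr_min


@dataclass
class GuidelineRule:
    """Ordered, exhaustive ideal-treatment bands.

    Default: HbA1c < 8 with preserved kidney function (eGFR >= 30) →
    metformin; HbA1c 8–9.5 → combined; HbA1c > 9.5 or eGFR < 30 →
    insulin. A catch-all insulin band makes the table exhaustive.
    """

    bands: list[GuidelineBand] = field(default_factory=list)

    @classmethod
    def default(cls) -> "GuidelineRule":
        return cls(
            bands=[
                GuidelineBand(ideal="metformin", hba1c_max=8.0, egfr_min=30.0),
                GuidelineBand(ideal="combined", hba1c_max=9.5, egfr_min=30.0),
                GuidelineBand(ideal="insulin"),
            ]
        )

    @classmethod
    def from_json(cls, path) -> "GuidelineRule":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        bands = [
            GuidelineBand(
                ideal=b["ideal"],
                hba1c_max=float(b.get("hba1c_max", "inf")),
                egfr_min=float(b.get("egfr_min", 0.0)),
            )
            for b in payload["bands"]
        ]
        return cls(bands=bands)


class NonExhaustiveRuleError(ValueError):
    pass


def ideal_treatment(hba1c: float, egfr: float, rule: GuidelineRule | None = None) -> str:
    """Guideline-ideal hypoglycemic class for the year (first match wins)."""
    if not (hba1c > 0 and egfr > 0):
        raise ValueError(f"hba1c and egfr must be positive, got {hba1c}, {egfr}")
    rule = rule or GuidelineRule.default()
    for band in rule.bands:
        if band.matches(hba1c, egfr):
            return band.ideal
    raise NonExhaustiveRuleError(
        f"no guideline band matches hba1c={hba1c}, egfr={egfr}; bands must be exhaustive"
    )


class UntreatedPatientsError(ValueError):
    pass


@dataclass
class AdherenceCrossTab:
    """3x3 ideal-by-actual counts with row percentages."""

    counts: np.ndarray
    row_percentages: np.ndarray

    def to_frame(self, *, percent: bool = True) -> pd.DataFrame:
        values = self.row_percentages if percent else self.counts
        return pd.DataFrame(values, index=TREATMENT_CLASSES, columns=TREATMENT_CLASSES)

    @property
    def diagonal_percentages(self) -> np.ndarray:
        return np.diag(self.row_percentages)


def cross_tab(ideal: Sequence[str], actual: Sequence[str]) -> AdherenceCrossTab:
    """Ideal-vs-prescribed cross-tabulation over treated patients.

    Rows are the ideal class, columns the prescribed class; row
    percentages sum to 100 for nonempty rows. Untreated patients
    ("none") must be filtered out by the caller first.
    """
    if len(ideal) != len(actual):
        raise ValueError("ideal and actual must be aligned")
    idx = {c: i for i, c in enumerate(TREATMENT_CLASSES)}
    counts = np.zeros((3, 3), dtype=int)
    for i_cls, a_cls in zip(ideal, actual):
        if i_cls not in idx or a_cls not in idx:
            raise UntreatedPatientsError(
                f"class pair ({i_cls!r}, {a_cls!r}) outside {TREATMENT_CLASSES}; "
                "filter untreated patients before cross-tabulating"
            )
        counts[idx[i_cls], idx[a_cls]] += 1
    pct = np.zeros((3, 3), dtype=float)
    for r in range(3):
        total = counts[r].sum()
        if total > 0:
            pct[r] = 100.0 * counts[r] / total
    return AdherenceCrossTab(counts=counts, row_percentages=pct)


def professional_adherence_flags(
    record: Mapping,
    *,
    rule: GuidelineRule | None = None,
    ldl_threshold: float = 100.0,
) -> dict[str, bool]:
    """Professional guideline-adherence flags for one labeled patient-year.

    ``hba1c_guide`` is true when the prescribed hypoglycemic class
    equals the guideline-ideal class (or a glycemic guideline marker was
    found in the note). ``cholesterol_guide`` is true when
    lipid-lowering treatment is present while LDL exceeds
    ``ldl_threshold`` mg/dL, vacuously when LDL is at or below it, or
    when a dyslipidemia guideline marker was found.
    """
    drugs = record.get("drugs") or []
    if isinstance(drugs, str):
        drugs = [d for d in drugs.split(";") if d]
    markers = set(record.get("guideline_markers") or [])
    actual = actual_treatment(drugs)
    ideal = ideal_treatment(record["hba1c"], record["egfr"], rule)
    hba1c_guide = actual == ideal or "hba1c_guideline" in markers
    has_lipid_drug = any(
        drug_class(d) == "lipid_lowering" for d in expand_combinations(drugs)
    )
    ldl = record.get("ldl_cholesterol")
    if "cholesterol_guideline" in markers:
        cholesterol_guide = True
    elif ldl is not None and not pd.isna(ldl) and ldl > ldl_threshold:
        cholesterol_guide = has_lipid_drug
    else:
        cholesterol_guide = True
    return {"hba1c_guide": hba1c_guide, "cholesterol_guide": cholesterol_guide}
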