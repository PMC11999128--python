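"""Stage assignment and transition-matrix estimation.

Each patient-year is assigned one of the four stages from three inputs:
the HbA1c measurement, a personalized goal threshold (6.5, 7.0 or 7.5 %
depending on age and complication history), and whether a staging
complication — retinopathy, cerebrovascular disease or chronic kidney
disease — has ever been coded. "Within goals" is strict: HbA1c exactly
at the threshold is out of goals. Complications are absorbing, so a
stage sequence may never step from a YES stage back to a NOT stage;
observing such a step in data is treated as a data-quality error, not
silently repaired.

Transition matrices are estimated as row-normalized count matrices over
aligned (start stage, end stage) pairs. The 1-year matrix pools both
adjacent-year pairs of a three-year panel; the 2-year matrix uses the
first-to-last pair.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stages import (
    STAGE_INDEX,
    STAGE_NAMES,
    STAGE_ORDER,
    STRUCTURAL_ZEROS,
    Stage,
    validate_transition_matrix,
)

ALLOWED_THRESHOLDS = (6.5, 7.0, 7.5)


@dataclass(frozen=True)
class GoalRule:
    """One first-match-wins rule: predicate(age, complications) -> threshold."""

    predicate: Callable[[float, frozenset], bool]
    threshold: float
    label: str = ""


@dataclass
class GoalPolicy:
    """Ordered personalized HbA1c-goal rules; first matching rule wins.

    The default policy maps younger uncomplicated patients to the strict
    6.5 % goal and older or complicated patients to the relaxed 7.5 %
    goal, with 7.0 % in between. It is an explicit, configurable
    operationalization of "personalized goals": guideline standards list
    the three thresholds but not a deterministic mapping.
    """

    rules: list[GoalRule] = field(default_factory=list)
    default_threshold: float = 7.0

    def __post_init__(self) -> None:
        for rule in self.rules:
            if rule.threshold not in ALLOWED_THRESHOLDS:
                raise ValueError(
                    f"threshold {rule.threshold} not in {ALLOWED_THRESHOLDS}"
                )

    @classmethod
    def default(cls) -> "GoalPolicy":
        return cls(
            rules=[
                GoalRule(
                    lambda age, comp: age >= 65 or bool(comp), 7.5, "elderly-or-complicated"
                ),
                GoalRule(lambda age, comp: age < 45 and not comp, 6.5, "young-uncomplicated"),
            ],
            default_threshold=7.0,
        )


def personal_goal(
    age: float, complications: Iterable[str], policy: GoalPolicy | None = None
) -> float:
    """Personalized HbA1c goal threshold (%) for a patient-year."""
    if age <= 0:
        raise ValueError(f"age must be positive, got {age}")
    policy = policy or GoalPolicy.default()
    comp = frozenset(complications)
    for rule in policy.rules:
        if rule.predicate(age, comp):
            return rule.threshold
    return policy.default_threshold


def assign_stage(hba1c: float, threshold: float, has_complication: bool) -> Stage:
    """Stage from HbA1c vs goal (strict ``<``) and complication status."""
    if not hba1c > 0:
        raise ValueError(f"HbA1c must be positive, got {hba1c}")
    return Stage.from_flags(on_goal=hba1c < threshold, has_complication=has_complication)


def load_icd10_staging_map(path=None) -> dict[str, list[str]]:
    """ICD-10 prefix lists for the three staging complications."""
    if path is None:
        ref = resources.files("dmtransit.data").joinpath("icd10_staging.json")
        with ref.open(encoding="utf-8") as fh:
            payload = json.load(fh)
    else:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    return {k: v for k, v in payload.items() if k != "comment"}


def codes_to_complications(
    codes: Iterable[str], icd10_map: Mapping[str, Sequence[str]]
) -> set[str]:
    """Map ICD-10 codes to staging-complication names by prefix match."""
    found = set()
    for code in codes:
        code = code.strip().upper()
        if not code:
            continue
        for complication, prefixes in icd10_map.items():
            if any(code.startswith(p.upper()) for p in prefixes):
                found.add(complication)
    return found


def complication_status(
    yearly_codes: Sequence[Iterable[str]],
    icd10_map: Mapping[str, Sequence[str]] | None = None,
) -> list[bool]:
    """Per-year absorbing complication indicator for one patient.

    ``yearly_codes`` is the patient's ICD-10 code lists sorted by year;
    the indicator turns true at the first year any staging complication
    appears and stays true onward.
    """
    icd10_map = icd10_map or load_icd10_staging_map()
    status, seen = [], False
    for codes in yearly_codes:
        if not seen and codes_to_complications(codes, icd10_map):
            seen = True
        status.append(seen)
    return status


class ForbiddenTransitionError(ValueError):
    """A stage sequence steps from a YES stage back to a NOT stage."""


def enforce_monotone(stages: Sequence[Stage]) -> Sequence[Stage]:
    """Validate that complications never regress along a stage sequence."""
    if len(stages) == 0:
        raise ValueError("empty stage sequence")
    for i in range(len(stages) - 1):
        if stages[i].has_complication and not stages[i + 1].has_complication:
            raise ForbiddenTransitionError(
                f"complication regression {stages[i].value} -> {stages[i + 1].value} "
                f"at step ({i + 1}, {i + 2})"
            )
    return stages


@dataclass
class TransitionMatrix:
    """Counts and row proportions over the fixed 4-stage ordering."""

    horizon_years: int
    counts: np.ndarray
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.proportions = np.asarray(self.proportions, dtype=float)
        for i in range(4):
            if self.counts[i].sum() > 0:
                s = self.proportions[i].sum()
                if abs(s - 1.0) > 1e-9:
                    raise ValueError(f"row {STAGE_NAMES[i]} proportions sum to {s}")

    def to_frame(self, *, percent: bool = False) -> pd.DataFrame:
        values = self.proportions * 100 if percent else self.proportions
        return pd.DataFrame(values, index=STAGE_NAMES, columns=STAGE_NAMES)

    def cell(self, start: Stage, end: Stage) -> float:
        return float(self.proportions[STAGE_INDEX[start], STAGE_INDEX[end]])

    def to_dict(self) -> dict:
        return {
            "horizon_years": self.horizon_years,
            "stages": list(STAGE_NAMES),
            "counts": self.counts.tolist(),
            "proportions": self.proportions.tolist(),
        }


def transition_matrix(
    states_t0: Sequence[Stage], states_th: Sequence[Stage], horizon: int
) -> TransitionMatrix:
    """Count matrix and row proportions from aligned start/end stages.

    Raises :class:`ForbiddenTransitionError` if any pair regresses from
    a complication stage to a no-complication stage.
    """
    if len(states_t0) != len(states_th):
        raise ValueError(
            f"aligned lists required: {len(states_t0)} starts vs {len(states_th)} ends"
        )
    counts = np.zeros((4, 4), dtype=int)
    for a, b in zip(states_t0, states_th):
        if a.has_complication and not b.has_complication:
            raise ForbiddenTransitionError(
                f"observed forbidden transition {a.value} -> {b.value}"
            )
        counts[STAGE_INDEX[a], STAGE_INDEX[b]] += 1
    proportions = np.zeros((4, 4), dtype=float)
    for i in range(4):
        row_total = counts[i].sum()
        if row_total > 0:
            proportions[i] = counts[i] / row_total
    for r, c in STRUCTURAL_ZEROS:
        assert proportions[r, c] == 0.0
    return TransitionMatrix(horizon_years=horizon, counts=counts, proportions=proportions)


def stage_cohort(
    records: pd.DataFrame,
    policy: GoalPolicy | None = None,
    icd10_map: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Assign stage, goal threshold and complication flag per patient-year.

    Expects columns ``patient_id, year, age, hba1c, icd10_codes`` (codes
    ``;``-joined). Rows with missing HbA1c get no stage (NaN) but still
    contribute their codes to the absorbing complication status.
    """
    policy = policy or GoalPolicy.default()
    icd10_map = icd10_map or load_icd10_staging_map()
    out = records.sort_values(["patient_id", "year"]).copy()
    thresholds, flags, stages = [], [], []
    for _, group in out.groupby("patient_id", sort=False):
        yearly_codes = [
            str(codes).split(";") if pd.notna(codes) else []
            for codes in group["icd10_codes"]
        ]
        status = complication_status(yearly_codes, icd10_map)
        comp_sets, seen = [], set()
        for codes in yearly_codes:
            seen |= codes_to_complications(codes, icd10_map)
            comp_sets.append(set(seen))
        for (_, row), has_comp, comps in zip(group.iterrows(), status, comp_sets):
            thr = personal_goal(row["age"], comps, policy)
            thresholds.append(thr)
            flags.append(has_comp)
            if pd.isna(row["hba1c"]):
                stages.append(None)
            else:
                stages.append(assign_stage(row["hba1c"], thr, has_comp).value)
    out["goal_threshold"] = thresholds
    out["has_complication"] = flags
    out["stage"] = stages
    return out


class InsufficientYearsError(ValueError):
    pass


def summarize_transitions(
    staged: pd.DataFrame, horizons: Sequence[int] = (1, 2)
) -> dict[int, TransitionMatrix]:
    """1- and 2-year transition matrices from a staged panel.

    The 1-year matrix pools every adjacent-year pair; the 2-year matrix
    pairs each year with the year two later. Patients lacking a stage in
    either year of a pair are excluded from that pair.
    """
    staged = staged.dropna(subset=["stage"])
    years = sorted(staged["year"].unique())
    by_year = {
        y: staged[staged["year"] == y].set_index("patient_id")["stage"] for y in years
    }
    result: dict[int, TransitionMatrix] = {}
    for horizon in horizons:
        pairs = [(y, y + horizon) for y in years if y + horizon in by_year]
        if not pairs:
            raise InsufficientYearsError(
                f"no year pairs at horizon {horizon} among years {years}"
            )
        starts: list[Stage] = []
        ends: list[Stage] = []
        for y0, y1 in pairs:
            s0, s1 = by_year[y0], by_year[y1]
            common = s0.index.intersection(s1.index)
            starts.extend(Stage(v) for v in s0.loc[common])
            ends.extend(Stage(v) for v in s1.loc[common])
        result[horizon] = transition_matrix(starts, ends, horizon)
    return result


def sd_or_zero(values: np.ndarray) -> float:
    """Sample SD; a single observation reports 0 with a warning."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < 2:
        warnings.warn("SD undefined for <2 observations; reporting 0", stacklevel=2)
        return 0.0
    return float(np.std(values, ddof=1))
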