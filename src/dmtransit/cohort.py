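"""Synthetic EHR-like cohorts with known ground truth.

The generator is a discrete-time four-stage Markov chain at one-year
steps with stage-conditional emission of biomarkers, treatment lists and
free-text clinical notes. Its defaults reproduce the reference cohort's
structure: the stage-conditional biomarker means/SDs and flag
prevalences, the observed 1- and 2-year transition matrices with
absorbing complications, and the 2018 initial stage distribution. Notes
are rendered from bilingual (Spanish-flavoured clinical shorthand with
English variants) templates stored as a data fixture, embedding the
drugs, conditions, adherence phrasing and lifestyle recommendations the
ground truth records — so every downstream stage (NLP extraction,
staging, adherence, prediction) can be tested against exact truth.

HbA1c is emitted from a truncated normal on the correct side of the
patient's personalized goal (strictly below for ON stages, at or above
for OUT stages); the location parameter is calibrated so the realized
stage-conditional mean matches the configured mean despite truncation.

An optional :class:`PlantedEffects` mode makes next-step transitions
depend on baseline covariates through logistic tilts of the goal and
complication margins — the testbed for parameter-recovery checks of the
prediction models. Plain Markov mode is unaffected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit, ndtr, ndtri

from . import nlp
from .adherence import GuidelineRule, ideal_treatment
from .nlp import Lexicon, default_lexicon
from .stages import (
    INITIAL_STAGE_PROBS,
    STAGE_ORDER,
    Stage,
    TRANSITIONS_1Y,
    TRANSITIONS_2Y,
    validate_transition_matrix,
)
from .staging import GoalPolicy, personal_goal

COMPLICATIONS = ("chronic kidney disease", "retinopathy", "cerebrovascular disease")
# Kidney disease dominates incident complications in this population.
COMPLICATION_WEIGHTS = (0.60, 0.25, 0.15)
COMPLICATION_CODES = {
    "chronic kidney disease": ("N18.3", "N18.4", "N18.9"),
    "retinopathy": ("E11.3", "H36.0"),
    "cerebrovascular disease": ("I63.9", "I61.0", "I67.8"),
}

# Stage order for all per-stage parameter vectors: ON-NOT, OUT-NOT, ON-YES, OUT-YES.
DEFAULT_BIOMARKER_PARAMS: dict[str, list[tuple[float, float]]] = {
    "age": [(69.34, 11.95), (64.96, 11.97), (70.41, 11.75), (65.91, 12.08)],
    "ldl_cholesterol": [(93.31, 38.01), (96.33, 40.88), (93.87, 37.81), (96.56, 39.73)],
    "egfr": [(76.83, 20.23), (81.04, 21.26), (77.55, 20.23), (82.80, 21.99)],
    "creatinine": [(0.93, 0.39), (0.91, 0.39), (0.92, 0.38), (0.90, 0.40)],
    "bmi": [(28.84, 4.79), (28.81, 4.76), (28.80, 4.79), (28.91, 4.78)],
    "weight": [(74.33, 14.47), (75.30, 14.79), (73.98, 14.50), (75.20, 14.57)],
    "height": [(1.60, 0.09), (1.61, 0.09), (1.60, 0.09), (1.61, 0.10)],
    "diastolic_bp": [(75.29, 7.64), (76.04, 7.64), (75.23, 7.51), (75.89, 7.63)],
    "systolic_bp": [(122.8, 11.47), (123.5, 12.03), (122.7, 11.38), (123.4, 11.93)],
    "hba1c": [(6.37, 0.49), (8.66, 1.57), (6.43, 0.46), (8.53, 1.49)],
}

DEFAULT_LABEL_PREVALENCES: dict[str, list[float]] = {
    "female": [0.60, 0.55, 0.59, 0.55],
    "patient_compliance": [0.12, 0.14, 0.15, 0.17],
    "cholesterol_guide": [0.005, 0.01, 0.005, 0.01],
    "hba1c_guide": [0.73, 0.41, 0.64, 0.48],
    "rec_physical": [0.79, 0.81, 0.78, 0.82],
    "rec_nutrition": [0.85, 0.89, 0.85, 0.91],
    "rec_tobacco": [0.07, 0.07, 0.05, 0.06],
    "rec_alcohol": [0.45, 0.48, 0.42, 0.47],
    "antihypertensive_mean": [1.11, 0.88, 1.17, 0.96],
    "analgesic": [0.16, 0.10, 0.16, 0.11],
    "antacid": [0.16, 0.13, 0.16, 0.14],
}

SECOND_LINE_DRUGS = ("empagliflozin", "dapagliflozin", "sitagliptin", "glibenclamide")
ANTIHYPERTENSIVES = (
    "enalapril",
    "losartan",
    "amlodipine",
    "metoprolol succinate",
    "losartan+hydrochlorothiazide",
)
STATINS = ("atorvastatin", "rosuvastatin")


class GenerationError(RuntimeError):
    """Note rendering cannot proceed (e.g. a template category is missing)."""


class ConfigurationError(ValueError):
    pass


@dataclass
class NoteNoise:
    """Corruption rates applied to rendered entity mentions.

    ``misspelling_rate`` — probability an entity mention is rendered
    with a single-character typo (edit distance exactly 1, kept uniquely
    correctable). ``abbreviation_rate`` — probability a condition with a
    clinical abbreviation ("HBP", "ERC") is rendered abbreviated.
    ``distractor_rate`` — inclusion probability of each of three
    non-entity filler phrases.
    """

    misspelling_rate: float = 0.05
    abbreviation_rate: float = 0.30
    distractor_rate: float = 0.30

    def validate(self) -> None:
        for name in ("misspelling_rate", "abbreviation_rate", "distractor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")


@dataclass
class PlantedEffects:
    """Logistic tilts of the transition margins by baseline covariates.

    ``goal_coefs`` shift the log-odds of being OUT of goals at the next
    step; ``comp_coefs`` shift the log-odds of developing a complication
    (for patients without one). Keys name binary record fields
    (``hba1c_guide``, ``non_compliant``, ``rec_nutrition`` ...). When in
    effect, the two margins are combined independently, so the joint
    4-stage law is no longer the configured matrix — this mode exists to
    plant recoverable covariate effects, not to match observed tables.
    """

    goal_coefs: dict[str, float] = field(default_factory=dict)
    comp_coefs: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortConfig:
    """Full specification of one synthetic cohort."""

    n_patients: int = 1000
    years: Sequence[int] = (2018, 2019, 2020)
    seed: int = 0
    initial_stage_probs: Sequence[float] = tuple(INITIAL_STAGE_PROBS)
    transition_matrix_1y: np.ndarray = field(default_factory=lambda: TRANSITIONS_1Y.copy())
    transition_matrix_2y: np.ndarray | None = field(
        default_factory=lambda: TRANSITIONS_2Y.copy()
    )
    biomarker_params: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_BIOMARKER_PARAMS.items()}
    )
    label_prevalences: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_LABEL_PREVALENCES.items()}
    )
    note_noise: NoteNoise = field(default_factory=NoteNoise)
    adherence_stated_rate: float = 0.8
    hide_structured_drugs_rate: float = 0.3
    missing_hba1c_rate: float = 0.0
    missing_predictor_rate: float = 0.0
    render_notes: bool = True
    planted_effects: PlantedEffects | None = None

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be nonnegative")
        if len(self.years) < 1 or list(self.years) != sorted(set(self.years)):
            raise ConfigurationError("years must be a strictly increasing nonempty list")
        probs = np.asarray(self.initial_stage_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ConfigurationError("initial_stage_probs must be a 4-vector summing to 1")
        validate_transition_matrix(self.transition_matrix_1y, name="transition_matrix_1y")
        if self.transition_matrix_2y is not None:
            validate_transition_matrix(
                self.transition_matrix_2y, name="transition_matrix_2y"
            )
        for var, params in self.biomarker_params.items():
            for mean, sd in params:
                if sd < 0:
                    raise ConfigurationError(f"negative SD for {var}")
        for var, prevs in self.label_prevalences.items():
            if var.endswith("_mean"):
                continue
            for p in prevs:
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"prevalence out of [0,1] for {var}")
        self.note_noise.validate()

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CohortConfig":
        payload = dict(payload)
        if "note_noise" in payload and isinstance(payload["note_noise"], Mapping):
            payload["note_noise"] = NoteNoise(**payload["note_noise"])
        if "planted_effects" in payload and isinstance(payload["planted_effects"], Mapping):
            payload["planted_effects"] = PlantedEffects(**payload["planted_effects"])
        for key in ("transition_matrix_1y", "transition_matrix_2y"):
            if key in payload and payload[key] is not None:
                m = np.asarray(payload[key], dtype=float)
                # config files carry rounded values; renormalize rows
                payload[key] = m / m.sum(axis=1, keepdims=True)
        if "biomarker_params" in payload:
            payload["biomarker_params"] = {
                k: [tuple(p) for p in v] for k, v in payload["biomarker_params"].items()
            }
        return cls(**payload)


def default_templates() -> dict:
    ref = resources.files("dmtransit.data").joinpath("templates.json")
    with ref.open(encoding="utf-8") as fh:
        return json.load(fh)


def sample_stage_path(
    initial: Stage,
    matrix: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
) -> list[Stage]:
    """Sample a stage path of length ``n_steps + 1`` from a Markov chain."""
    m = validate_transition_matrix(matrix)
    path = [initial]
    state = initial
    for _ in range(n_steps):
        row = m[STAGE_ORDER.index(state)]
        state = STAGE_ORDER[rng.choice(4, p=row)]
        path.append(state)
    return path


# ---------------------------------------------------------------------------
# note rendering


@dataclass(frozen=True)
class Mention:
    canonical: str
    category: str
    surface: str  # lexicon surface chosen
    rendered: str  # what actually appears in the note (possibly misspelled)
    misspelled: bool


@dataclass
class RenderedNote:
    text: str
    mentions: list[Mention]

    def __str__(self) -> str:
        return self.text


_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _misspell_word(word: str, lexicon: Lexicon, rng: np.random.Generator) -> str | None:
    """Single-character edit that corrects uniquely back to ``word``."""
    for _ in range(30):
        op = int(rng.integers(3))
        pos = int(rng.integers(len(word)))
        if op == 0 and len(word) > 3:
            cand = word[:pos] + word[pos + 1 :]
        elif op == 1:
            cand = word[:pos] + _LETTERS[int(rng.integers(26))] + word[pos:]
        else:
            letter = _LETTERS[int(rng.integers(26))]
            if letter == word[pos]:
                continue
            cand = word[:pos] + letter + word[pos + 1 :]
        if cand == word or len(cand) < 2:
            continue
        if cand in lexicon._vocab_set:
            continue
        if nlp.correct_spelling(cand, lexicon) == word:
            return cand
    return None


def _render_surface(
    entry: nlp.LexiconEntry,
    lexicon: Lexicon,
    noise: NoteNoise,
    rng: np.random.Generator,
) -> tuple[str, bool]:
    words = list(entry.surface_tokens)
    misspelled = False
    if rng.random() < noise.misspelling_rate:
        long_idx = [i for i, w in enumerate(words) if len(w) >= 4] or list(range(len(words)))
        idx = long_idx[int(rng.integers(len(long_idx)))]
        typo = _misspell_word(words[idx], lexicon, rng)
        if typo is not None:
            words[idx] = typo
            misspelled = True
    return " ".join(words), misspelled


def _pick_entry(
    canonical: str,
    category: str,
    lexicon: Lexicon,
    noise: NoteNoise,
    rng: np.random.Generator,
) -> nlp.LexiconEntry:
    entries = lexicon.surfaces_for(canonical, category)
    if not entries:
        raise GenerationError(f"lexicon has no surface for {category}:{canonical}")
    abbrevs = [e for e in entries if e.abbrev]
    full = [e for e in entries if not e.abbrev]
    if abbrevs and (not full or rng.random() < noise.abbreviation_rate):
        pool = abbrevs
    else:
        pool = full or abbrevs
    return pool[int(rng.integers(len(pool)))]


def render_note(
    state: Mapping,
    templates: Mapping,
    noise: NoteNoise,
    rng: np.random.Generator,
    lexicon: Lexicon | None = None,
) -> RenderedNote:
    """Render one clinical note from a per-year ground-truth state.

    ``state`` carries ``age``, ``conditions`` and ``drugs`` (canonical
    names), ``adherence`` (compliant / non_compliant / unstated),
    ``recommendations`` (category -> bool) and ``guideline_markers``.
    Every ground-truth entity is embedded through some lexicon surface
    form, corrupted per ``noise``; adherence phrasing appears iff the
    status is stated.
    """
    lexicon = lexicon or default_lexicon()

    def pick_template(category: str) -> str:
        options = templates.get(category)
        if not options:
            raise GenerationError(f"no note template for category {category!r}")
        return options[int(rng.integers(len(options)))]

    mentions: list[Mention] = []
    sentences: list[str] = []

    def add_entity(canonical: str, category: str, template_key: str, **extra) -> None:
        entry = _pick_entry(canonical, category, lexicon, noise, rng)
        rendered, misspelled = _render_surface(entry, lexicon, noise, rng)
        sentence = pick_template(template_key).format(e=rendered, **extra)
        sentences.append(sentence)
        mentions.append(
            Mention(
                canonical=canonical,
                category=category,
                surface=entry.surface,
                rendered=rendered,
                misspelled=misspelled,
            )
        )

    sentences.append(pick_template("intro").format(age=int(state.get("age", 60))))
    distractors = list(templates.get("distractors", []))

    def maybe_distract() -> None:
        if distractors and rng.random() < noise.distractor_rate:
            sentences.append(distractors[int(rng.integers(len(distractors)))])

    for condition in state.get("conditions", ()):
        add_entity(condition, "condition", "condition")
    maybe_distract()
    doses = templates.get("doses", [""])
    for drug in state.get("drugs", ()):
        add_entity(drug, "drug", "drug", dose=doses[int(rng.integers(len(doses)))])
    maybe_distract()
    adherence = state.get("adherence", nlp.ADHERENCE_UNSTATED)
    if adherence != nlp.ADHERENCE_UNSTATED:
        canonical = (
            "non_adherence" if adherence == nlp.ADHERENCE_NON_COMPLIANT else "good_adherence"
        )
        category = (
            "adherence_negative"
            if adherence == nlp.ADHERENCE_NON_COMPLIANT
            else "adherence_positive"
        )
        add_entity(canonical, category, "adherence")
    for category, flagged in state.get("recommendations", {}).items():
        if flagged:
            entries = lexicon.entries_for(f"recommendation_{category}")
            if not entries:
                raise GenerationError(f"lexicon has no recommendation surfaces: {category}")
            canonical = entries[0].canonical
            add_entity(canonical, f"recommendation_{category}", "recommendation")
    for marker in state.get("guideline_markers", ()):
        add_entity(marker, "guideline_marker", "guideline_marker")
    maybe_distract()
    sentences.append(pick_template("closing"))
    return RenderedNote(text=". ".join(sentences) + ".", mentions=mentions)


# ---------------------------------------------------------------------------
# emission helpers


_CALIBRATION_CACHE: dict[tuple[float, float, float, float], float] = {}


def _calibrated_truncnorm(
    target_mean: float,
    sd: float,
    lower: float,
    upper: float,
    rng: np.random.Generator,
) -> float:
    """Draw from a truncated normal whose mean equals ``target_mean``.

    The location parameter is solved (and cached) so that truncation at
    the goal threshold does not bias the realized stage-conditional
    mean. If the target is unattainable inside the interval, the
    midpoint-anchored draw is used as-is.
    """
    def trunc_mean(mu: float) -> float:
        a, b = (lower - mu) / sd, (upper - mu) / sd
        fa, fb = ndtr(a), ndtr(b)
        phi = lambda z: np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi)
        return mu + sd * (phi(a) - phi(b)) / max(fb - fa, 1e-300)

    key = (target_mean, sd, lower, upper)
    loc = _CALIBRATION_CACHE.get(key)
    if loc is None:
        lo, hi = target_mean - 8 * sd, target_mean + 8 * sd
        try:
            loc = brentq(lambda mu: trunc_mean(mu) - target_mean, lo, hi, xtol=1e-6)
        except ValueError:
            loc = target_mean
        _CALIBRATION_CACHE[key] = loc
    fa = ndtr((lower - loc) / sd)
    fb = ndtr((upper - loc) / sd)
    u = rng.uniform(fa, fb)
    return float(loc + sd * ndtri(u))


def _draw_hba1c(
    stage: Stage, threshold: float, params: Sequence[tuple[float, float]], rng
) -> float:
    mean, sd = params[STAGE_ORDER.index(stage)]
    if stage.on_goal:
        value = _calibrated_truncnorm(mean, sd, 4.0, threshold, rng)
        return min(round(value, 2), threshold - 0.01)
    value = _calibrated_truncnorm(mean, sd, threshold, 16.0, rng)
    return max(round(value, 2), threshold)


_BIOMARKER_BOUNDS = {
    "ldl_cholesterol": (20.0, 300.0),
    "egfr": (5.0, 150.0),
    "creatinine": (0.3, 8.0),
    "bmi": (15.0, 55.0),
    "weight": (35.0, 160.0),
    "height": (1.35, 2.0),
    "diastolic_bp": (40.0, 130.0),
    "systolic_bp": (80.0, 220.0),
}


def _draw_biomarker(name: str, stage_idx: int, params: Mapping, rng) -> float:
    mean, sd = params[name][stage_idx]
    lo, hi = _BIOMARKER_BOUNDS[name]
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _tilted_step(
    row: np.ndarray,
    current: Stage,
    covariates: Mapping[str, float],
    effects: PlantedEffects,
    rng: np.random.Generator,
) -> Stage:
    """One planted-effects transition: tilt margins, recombine independently."""

    def tilt(p: float, coefs: Mapping[str, float]) -> float:
        shift = sum(c * float(covariates.get(f, 0.0)) for f, c in coefs.items())
        return float(expit(logit(np.clip(p, 1e-6, 1 - 1e-6)) + shift))

    p_out = tilt(row[1] + row[3], effects.goal_coefs)
    out_next = rng.random() < p_out
    if current.has_complication:
        comp_next = True
    else:
        p_comp = tilt(row[2] + row[3], effects.comp_coefs)
        comp_next = rng.random() < p_comp
    return Stage.from_flags(on_goal=not out_next, has_complication=comp_next)


# ---------------------------------------------------------------------------
# main generator


RECORD_COLUMNS = [
    "patient_id",
    "year",
    "age",
    "sex",
    "hba1c",
    "ldl_cholesterol",
    "egfr",
    "creatinine",
    "bmi",
    "weight",
    "height",
    "diastolic_bp",
    "systolic_bp",
    "icd10_codes",
    "drugs_structured",
    "referral_ophthalmology",
    "note_text",
]

TRUTH_COLUMNS = [
    "patient_id",
    "year",
    "stage",
    "goal_threshold",
    "complications",
    "conditions",
    "drugs",
    "adherence",
    "compliant",
    "non_compliant",
    "hba1c_guide",
    "cholesterol_guide",
    "rec_nutrition",
    "rec_physical",
    "rec_alcohol",
    "rec_tobacco",
    "ideal_treatment",
    "actual_treatment",
    "guideline_markers",
    "drugs_hidden",
    "misspelled_mentions",
    "total_mentions",
]


def generate_cohort(
    config: CohortConfig,
    lexicon: Lexicon | None = None,
    templates: Mapping | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort and its ground truth.

    Returns ``(records, truth)``: one row per patient per year in each.
    ``records`` is the observable EHR-like table (structured fields plus
    ``note_text``); ``truth`` stores the generating stage path, entity
    lists and flags. Identical config (including seed) yields identical
    output.
    """
    config.validate()
    lexicon = lexicon or default_lexicon()
    templates = templates or default_templates()
    rng = np.random.default_rng(config.seed)
    policy = GoalPolicy.default()
    guideline = GuidelineRule.default()
    years = list(config.years)
    prevalences = config.label_prevalences
    biomarkers = config.biomarker_params

    records: list[dict] = []
    truths: list[dict] = []

    for pid in range(config.n_patients):
        initial_idx = int(rng.choice(4, p=np.asarray(config.initial_stage_probs)))
        stage = STAGE_ORDER[initial_idx]
        female = rng.random() < prevalences["female"][initial_idx]
        age0 = int(np.clip(rng.normal(*biomarkers["age"][initial_idx]), 25, 95))
        complications: list[str] = []
        if stage.has_complication:
            complications.append(
                COMPLICATIONS[rng.choice(3, p=COMPLICATION_WEIGHTS)]
            )
        for step, year in enumerate(years):
            stage_idx = STAGE_ORDER.index(stage)
            age = age0 + (year - years[0])
            threshold = personal_goal(age, complications, policy)
            hba1c = _draw_hba1c(stage, threshold, biomarkers["hba1c"], rng)
            values = {
                name: _draw_biomarker(name, stage_idx, biomarkers, rng)
                for name in _BIOMARKER_BOUNDS
            }

            stated = rng.random() < config.adherence_stated_rate
            compliant = rng.random() < prevalences["patient_compliance"][stage_idx]
            adherence = (
                (nlp.ADHERENCE_COMPLIANT if compliant else nlp.ADHERENCE_NON_COMPLIANT)
                if stated
                else nlp.ADHERENCE_UNSTATED
            )
            recommendations = {
                "nutrition": rng.random() < prevalences["rec_nutrition"][stage_idx],
                "physical": rng.random() < prevalences["rec_physical"][stage_idx],
                "alcohol": rng.random() < prevalences["rec_alcohol"][stage_idx],
                "tobacco": rng.random() < prevalences["rec_tobacco"][stage_idx],
            }
            hba1c_guide = rng.random() < prevalences["hba1c_guide"][stage_idx]
            cholesterol_guide = rng.random() < prevalences["cholesterol_guide"][stage_idx]

            ideal = ideal_treatment(hba1c, values["egfr"], guideline)
            if hba1c_guide:
                actual = ideal
            else:
                others = [c for c in ("metformin", "combined", "insulin") if c != ideal]
                actual = others[int(rng.integers(2))]
            drugs: list[str] = []
            if actual == "metformin":
                drugs.append("metformin")
            elif actual == "combined":
                if rng.random() < 0.3:
                    drugs.append("empagliflozin+metformin")
                else:
                    drugs.extend(
                        ["metformin", SECOND_LINE_DRUGS[int(rng.integers(4))]]
                    )
            else:
                drugs.append("insulin glargine")
                if rng.random() < 0.4:
                    drugs.append("insulin aspart")
                if rng.random() < 0.3:
                    drugs.append("metformin")
            n_antihyp = min(int(rng.poisson(prevalences["antihypertensive_mean"][stage_idx])), 3)
            if n_antihyp:
                picks = rng.choice(len(ANTIHYPERTENSIVES), size=n_antihyp, replace=False)
                drugs.extend(ANTIHYPERTENSIVES[i] for i in sorted(picks))
            if cholesterol_guide:
                drugs.append(STATINS[int(rng.integers(2))])
            if rng.random() < prevalences["analgesic"][stage_idx]:
                drugs.append("acetaminophen")
            if rng.random() < prevalences["antacid"][stage_idx]:
                drugs.append("omeprazole")

            conditions = (["hypertension"] if n_antihyp else []) + list(complications)
            markers = []
            if cholesterol_guide:
                markers.append("cholesterol_guideline")
            if hba1c_guide and rng.random() < 0.5:
                markers.append("hba1c_guideline")

            codes = [
                COMPLICATION_CODES[c][int(rng.integers(len(COMPLICATION_CODES[c])))]
                for c in complications
            ]

            note_text = ""
            misspelled = total = 0
            if config.render_notes:
                rendered = render_note(
                    {
                        "age": age,
                        "conditions": conditions,
                        "drugs": drugs,
                        "adherence": adherence,
                        "recommendations": recommendations,
                        "guideline_markers": markers,
                    },
                    templates,
                    config.note_noise,
                    rng,
                    lexicon,
                )
                note_text = rendered.text
                total = len(rendered.mentions)
                misspelled = sum(m.misspelled for m in rendered.mentions)

            drugs_hidden = rng.random() < config.hide_structured_drugs_rate
            hba1c_missing = rng.random() < config.missing_hba1c_rate
            predictor_missing = rng.random() < config.missing_predictor_rate

            records.append(
                {
                    "patient_id": pid,
                    "year": year,
                    "age": age,
                    "sex": "F" if female else "M",
                    "hba1c": np.nan if hba1c_missing else hba1c,
                    "ldl_cholesterol": np.nan
                    if predictor_missing
                    else round(values["ldl_cholesterol"], 1),
                    "egfr": round(values["egfr"], 1),
                    "creatinine": round(values["creatinine"], 2),
                    "bmi": round(values["bmi"], 1),
                    "weight": round(values["weight"], 1),
                    "height": round(values["height"], 2),
                    "diastolic_bp": round(values["diastolic_bp"], 0),
                    "systolic_bp": round(values["systolic_bp"], 0),
                    "icd10_codes": ";".join(codes),
                    "drugs_structured": "" if drugs_hidden else ";".join(drugs),
                    "referral_ophthalmology": bool(rng.random() < 0.3),
                    "note_text": note_text,
                }
            )
            truths.append(
                {
                    "patient_id": pid,
                    "year": year,
                    "stage": stage.value,
                    "goal_threshold": threshold,
                    "complications": list(complications),
                    "conditions": conditions,
                    "drugs": list(drugs),
                    "adherence": adherence,
                    "compliant": compliant,
                    "non_compliant": adherence == nlp.ADHERENCE_NON_COMPLIANT,
                    "hba1c_guide": hba1c_guide,
                    "cholesterol_guide": cholesterol_guide,
                    "rec_nutrition": recommendations["nutrition"],
                    "rec_physical": recommendations["physical"],
                    "rec_alcohol": recommendations["alcohol"],
                    "rec_tobacco": recommendations["tobacco"],
                    "ideal_treatment": ideal,
                    "actual_treatment": actual,
                    "guideline_markers": markers,
                    "drugs_hidden": drugs_hidden,
                    "misspelled_mentions": misspelled,
                    "total_mentions": total,
                }
            )

            if step == len(years) - 1:
                break
            gap = years[step + 1] - year
            if gap == 1:
                matrix = config.transition_matrix_1y
            elif gap == 2 and config.transition_matrix_2y is not None:
                matrix = config.transition_matrix_2y
            else:
                matrix = None  # chain 1-year draws
            covariates = {
                "hba1c_guide": float(hba1c_guide),
                "cholesterol_guide": float(cholesterol_guide),
                "non_compliant": float(adherence == nlp.ADHERENCE_NON_COMPLIANT),
                "rec_nutrition": float(recommendations["nutrition"]),
                "rec_physical": float(recommendations["physical"]),
            }
            if matrix is not None:
                row = matrix[STAGE_ORDER.index(stage)]
                if config.planted_effects is not None:
                    stage = _tilted_step(
                        row, stage, covariates, config.planted_effects, rng
                    )
                else:
                    stage = STAGE_ORDER[int(rng.choice(4, p=row))]
            else:
                for _ in range(gap):
                    row = config.transition_matrix_1y[STAGE_ORDER.index(stage)]
                    if config.planted_effects is not None:
                        stage = _tilted_step(
                            row, stage, covariates, config.planted_effects, rng
                        )
                    else:
                        stage = STAGE_ORDER[int(rng.choice(4, p=row))]
            if stage.has_complication and not complications:
                complications.append(
                    COMPLICATIONS[rng.choice(3, p=COMPLICATION_WEIGHTS)]
                )

    records_df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    truth_df = pd.DataFrame(truths, columns=TRUTH_COLUMNS)
    return records_df, truth_df


def summarize_cohort(records: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-stage means/SDs of biomarkers and prevalences of flags.

    One row per stage present in the cohort; used to verify generator
    calibration against the configured stage-conditional parameters.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    merged = records.merge(
        truth[
            [
                "patient_id",
                "year",
                "stage",
                "compliant",
                "hba1c_guide",
                "cholesterol_guide",
                "rec_nutrition",
                "rec_physical",
                "rec_alcohol",
                "rec_tobacco",
            ]
        ],
        on=["patient_id", "year"],
    )
    continuous = [
        "age",
        "ldl_cholesterol",
        "egfr",
        "creatinine",
        "bmi",
        "weight",
        "height",
        "diastolic_bp",
        "systolic_bp",
        "hba1c",
    ]
    flags = [
        "compliant",
        "hba1c_guide",
        "cholesterol_guide",
        "rec_nutrition",
        "rec_physical",
        "rec_alcohol",
        "rec_tobacco",
    ]
    from .staging import sd_or_zero

    rows = {}
    for stage_name, group in merged.groupby("stage"):
        row = {"n": len(group), "female": float((group["sex"] == "F").mean())}
        for var in continuous:
            row[f"{var}_mean"] = float(group[var].mean())
            row[f"{var}_sd"] = sd_or_zero(group[var].to_numpy())
        for flag in flags:
            row[flag] = float(group[flag].mean())
        rows[stage_name] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


# ---------------------------------------------------------------------------
# persistence


def write_cohort(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=[""]).astype(
        {"note_text": str}
    )


def write_truth(truth: pd.DataFrame, path) -> None:
    """Ground truth as JSON Lines, one object per patient-year."""
    with open(path, "w", encoding="utf-8") as fh:
        for record in truth.to_dict(orient="records"):
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")


def read_truth(path) -> pd.DataFrame:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rows.append(json.loads(line))
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)
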