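"""Dictionary-driven extraction of structured labels from clinical notes.

Free-text outpatient notes carry information that is missing from the
structured EHR fields: drugs actually taken, comorbid conditions written
as abbreviations ("HBP" for hypertension), the physician's judgement of
the patient's pharmacological adherence, and lifestyle recommendations.
This module turns a note into structured labels with a deliberately
simple, auditable pipeline:

1. :func:`preprocess` — lowercase, accent-fold, strip URLs / digits /
   punctuation, drop stopwords;
2. :func:`correct_spelling` — map tokens to the unique lexicon token
   within edit distance 1, if any;
3. :func:`simple_search` — greedy longest-match n-gram scan over a
   curated medical lexicon;
4. :func:`classify_adherence` — polarity of matched adherence phrases
   with a small negation window;
5. :func:`extract_record` — the composition, returning an
   :class:`ExtractionResult`;
6. :func:`merge_structured` — backfill of missing structured fields.

The lexicon is data, not code: a JSON file listing surface forms (with
Spanish and English variants and clinical abbreviations), canonical
entity names, and categories. A fixture lexicon covering the package's
synthetic cohorts ships in :mod:`dmtransit.data`.
"""

from __future__ import annotations

import json
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

ADHERENCE_COMPLIANT = "compliant"
ADHERENCE_NON_COMPLIANT = "non_compliant"
ADHERENCE_UNSTATED = "unstated"

ENTITY_CATEGORIES = (
    "drug",
    "condition",
    "adherence_negative",
    "adherence_positive",
    "recommendation_nutrition",
    "recommendation_physical",
    "recommendation_alcohol",
    "recommendation_tobacco",
    "guideline_marker",
)
RECOMMENDATION_CATEGORIES = (
    "recommendation_nutrition",
    "recommendation_physical",
    "recommendation_alcohol",
    "recommendation_tobacco",
)

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_DIGIT_RE = re.compile(r"\d+")
_NON_ALPHA_RE = re.compile(r"[^a-z]+")


class LexiconError(ValueError):
    """Invalid lexicon content (duplicate surface forms, bad category)."""


def fold_accents(text: str) -> str:
    """Strip combining diacritics: ``"adherencía" -> "adherencia"``."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def preprocess(
    text: str,
    stopwords: Iterable[str] = (),
    *,
    min_token_len: int = 2,
) -> list[str]:
    """Normalize a raw note into a token sequence.

    Lowercases, folds accents, removes URLs, digits and punctuation,
    drops stopwords and tokens shorter than ``min_token_len``. Token
    order is preserved; an empty note yields an empty list. The output
    is a fixed point: re-running on ``" ".join(tokens)`` returns the
    same tokens.
    """
    if not text:
        return []
    stop = set(stopwords)
    cleaned = _URL_RE.sub(" ", text)
    cleaned = fold_accents(cleaned).lower()
    cleaned = _DIGIT_RE.sub("", cleaned)
    cleaned = _NON_ALPHA_RE.sub(" ", cleaned)
    return [
        tok
        for tok in cleaned.split()
        if len(tok) >= min_token_len and tok not in stop
    ]


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    canonical: str
    category: str
    abbrev: bool = False

    @property
    def surface_tokens(self) -> tuple[str, ...]:
        return tuple(fold_accents(self.surface).lower().split())


@dataclass
class Lexicon:
    """Surface-form → (canonical entity, category) dictionary.

    Surface forms must be unique after normalization; each may span up
    to ``max_ngram`` tokens. ``stopwords`` feed :func:`preprocess` so
    that surface forms and note tokens live in the same normalization.
    """

    entries: list[LexiconEntry]
    stopwords: set[str] = field(default_factory=set)
    max_ngram: int = 3

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, ...], LexiconEntry] = {}
        for entry in self.entries:
            if entry.category not in ENTITY_CATEGORIES:
                raise LexiconError(
                    f"unknown category {entry.category!r} for surface {entry.surface!r}"
                )
            key = entry.surface_tokens
            if not key:
                raise LexiconError(f"surface form {entry.surface!r} normalizes to nothing")
            if len(key) > self.max_ngram:
                raise LexiconError(
                    f"surface form {entry.surface!r} exceeds max_ngram={self.max_ngram}"
                )
            if key in self._index:
                raise LexiconError(f"duplicate surface form after normalization: {key}")
            self._index[key] = entry
        self._vocabulary = sorted({tok for key in self._index for tok in key})
        self._vocab_set = set(self._vocabulary)
        # token -> correction memo; valid because the vocabulary is fixed
        self._correction_cache: dict[str, str] = {}

    @property
    def token_vocabulary(self) -> list[str]:
        """Sorted unique single tokens occurring in any surface form."""
        return self._vocabulary

    def surface_index(self) -> Mapping[tuple[str, ...], LexiconEntry]:
        return self._index

    def entries_for(self, category: str) -> list[LexiconEntry]:
        return [e for e in self.entries if e.category == category]

    def surfaces_for(self, canonical: str, category: str | None = None) -> list[LexiconEntry]:
        return [
            e
            for e in self.entries
            if e.canonical == canonical and (category is None or e.category == category)
        ]

    @classmethod
    def from_json(cls, source) -> "Lexicon":
        """Load from a JSON file path or file-like object."""
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            with open(source, encoding="utf-8") as fh:
                payload = json.load(fh)
        entries = [
            LexiconEntry(
                surface=e["surface"],
                canonical=e["canonical"],
                category=e["category"],
                abbrev=bool(e.get("abbrev", False)),
            )
            for e in payload["entries"]
        ]
        return cls(
            entries=entries,
            stopwords=set(payload.get("stopwords", [])),
            max_ngram=int(payload.get("max_ngram", 3)),
        )

    def to_json(self, path) -> None:
        payload = {
            "max_ngram": self.max_ngram,
            "stopwords": sorted(self.stopwords),
            "entries": [
                {
                    "surface": e.surface,
                    "canonical": e.canonical,
                    "category": e.category,
                    **({"abbrev": True} if e.abbrev else {}),
                }
                for e in self.entries
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, ensure_ascii=False)


def default_lexicon() -> Lexicon:
    """The fixture lexicon shipped with the package."""
    ref = resources.files("dmtransit.data").joinpath("lexicon.json")
    with ref.open(encoding="utf-8") as fh:
        return Lexicon.from_json(fh)


def edit_distance(a: str, b: str, *, k: int = -1) -> int:
    """Levenshtein distance via edlib; ``-1`` if it exceeds bound ``k``."""
    return edlib.align(a, b, mode="NW", k=k)["editDistance"]


def correct_spelling(token: str, lexicon: Lexicon) -> str:
    """Correct a token against the lexicon's token vocabulary.

    An exact vocabulary token is returned unchanged (exact match wins).
    Otherwise, if exactly one vocabulary token lies within edit distance
    1, it is returned; ambiguity (two candidates) or no candidate leaves
    the token untouched.
    """
    if token in lexicon._vocab_set:
        return token
    cached = lexicon._correction_cache.get(token)
    if cached is not None:
        return cached
    candidates = []
    for vocab_tok in lexicon.token_vocabulary:
        if abs(len(vocab_tok) - len(token)) > 1:
            continue
        if edit_distance(token, vocab_tok, k=1) == 1:
            candidates.append(vocab_tok)
            if len(candidates) > 1:
                break
    result = candidates[0] if len(candidates) == 1 else token
    lexicon._correction_cache[token] = result
    return result


def correct_tokens(tokens: Sequence[str], lexicon: Lexicon) -> list[str]:
    return [correct_spelling(tok, lexicon) for tok in tokens]


@dataclass(frozen=True)
class MatchedSpan:
    """One lexicon hit: token range ``[start, end)`` and its entry."""

    start: int
    end: int
    surface: str
    canonical: str
    category: str


def simple_search(tokens: Sequence[str], lexicon: Lexicon) -> list[MatchedSpan]:
    """Greedy longest-match n-gram scan, left to right, no overlaps.

    At each position the longest lexicon surface form (up to
    ``max_ngram`` tokens) starting there is matched, so a combination
    product like ``losartan hydrochlorothiazide`` wins over its
    component ``losartan``.
    """
    index = lexicon.surface_index()
    spans: list[MatchedSpan] = []
    i, n = 0, len(tokens)
    while i < n:
        hit = None
        for width in range(min(lexicon.max_ngram, n - i), 0, -1):
            entry = index.get(tuple(tokens[i : i + width]))
            if entry is not None:
                hit = (width, entry)
                break
        if hit is None:
            i += 1
            continue
        width, entry = hit
        spans.append(
            MatchedSpan(
                start=i,
                end=i + width,
                surface=" ".join(tokens[i : i + width]),
                canonical=entry.canonical,
                category=entry.category,
            )
        )
        i += width
    return spans


def bow_vector(tokens: Sequence[str], lexicon: Lexicon) -> np.ndarray:
    """Bag-of-words counts of note tokens over the lexicon vocabulary."""
    counts = Counter(tokens)
    return np.array([counts[tok] for tok in lexicon.token_vocabulary], dtype=int)


@dataclass
class AdherencePatterns:
    """Polarity rules for pharmacological-adherence phrases.

    A matched adherence span *fires* unless a negation term occurs
    within ``window`` tokens on either side of it (tokens inside the
    span itself are ignored, so a phrase like ``"no adherencia"`` is not
    self-negated). Negative spans take precedence over positive ones.
    """

    negation_terms: set[str] = field(
        default_factory=lambda: {"no", "not", "non", "sin", "niega", "denies", "without"}
    )
    window: int = 4

    def is_negated(self, tokens: Sequence[str], span: MatchedSpan) -> bool:
        before = tokens[max(0, span.start - self.window) : span.start]
        after = tokens[span.end : span.end + self.window]
        return any(tok in self.negation_terms for tok in (*before, *after))


def classify_adherence(
    tokens: Sequence[str],
    spans: Sequence[MatchedSpan],
    patterns: AdherencePatterns | None = None,
) -> str:
    """Classify pharmacological adherence from matched adherence spans."""
    patterns = patterns or AdherencePatterns()
    fired = {"adherence_negative": False, "adherence_positive": False}
    for span in spans:
        if span.category in fired and not patterns.is_negated(tokens, span):
            fired[span.category] = True
    if fired["adherence_negative"]:
        return ADHERENCE_NON_COMPLIANT
    if fired["adherence_positive"]:
        return ADHERENCE_COMPLIANT
    return ADHERENCE_UNSTATED


@dataclass
class ExtractionResult:
    """Structured labels extracted from one note."""

    conditions: set[str]
    drugs: set[str]
    adherence: str
    recommendations: dict[str, bool]
    guideline_markers: set[str]
    matched_spans: list[MatchedSpan]

    @property
    def is_empty(self) -> bool:
        return not self.matched_spans


def extract_record(
    note: str,
    lexicon: Lexicon,
    patterns: AdherencePatterns | None = None,
    *,
    correct: bool = True,
) -> ExtractionResult:
    """Run the full pipeline on one note.

    ``correct=False`` disables edit-distance-1 spelling correction
    (useful to quantify its contribution on noisy notes).
    """
    tokens = preprocess(note, lexicon.stopwords)
    if correct:
        tokens = correct_tokens(tokens, lexicon)
    spans = simple_search(tokens, lexicon)
    recommendations = {cat: False for cat in RECOMMENDATION_CATEGORIES}
    conditions: set[str] = set()
    drugs: set[str] = set()
    markers: set[str] = set()
    for span in spans:
        if span.category == "condition":
            conditions.add(span.canonical)
        elif span.category == "drug":
            drugs.add(span.canonical)
        elif span.category in recommendations:
            recommendations[span.category] = True
        elif span.category == "guideline_marker":
            markers.add(span.canonical)
    return ExtractionResult(
        conditions=conditions,
        drugs=drugs,
        adherence=classify_adherence(tokens, spans, patterns),
        recommendations=recommendations,
        guideline_markers=markers,
        matched_spans=spans,
    )


class SchemaError(TypeError):
    """Structured row does not expose the expected fields."""


def merge_structured(row: Mapping, extraction: ExtractionResult) -> dict:
    """Backfill a structured patient-year row with extracted labels.

    Set-valued fields (drugs, conditions) take the union; scalar flags
    keep the structured value when present and log a conflict when the
    text disagrees. A provenance map records where each value came from.
    """
    if not isinstance(row, Mapping):
        raise SchemaError(f"expected a mapping row, got {type(row).__name__}")
    merged = dict(row)
    provenance: dict[str, str] = {}
    conflicts: list[str] = []

    def _split(value) -> set[str]:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return set()
        if isinstance(value, str):
            return {v.strip() for v in value.split(";") if v.strip()}
        return set(value)

    for column, extracted in (
        ("drugs_structured", extraction.drugs),
        ("conditions_structured", extraction.conditions),
    ):
        structured = _split(merged.get(column))
        union = structured | set(extracted)
        if union != structured:
            provenance[column] = "nlp" if not structured else "both"
        elif structured:
            provenance[column] = "structured"
        merged[column] = ";".join(sorted(union))

    structured_adherence = merged.get("adherence")
    if structured_adherence in (None, "", ADHERENCE_UNSTATED) or (
        isinstance(structured_adherence, float) and np.isnan(structured_adherence)
    ):
        merged["adherence"] = extraction.adherence
        if extraction.adherence != ADHERENCE_UNSTATED:
            provenance["adherence"] = "nlp"
    else:
        provenance["adherence"] = "structured"
        if (
            extraction.adherence != ADHERENCE_UNSTATED
            and extraction.adherence != structured_adherence
        ):
            conflicts.append(
                f"adherence: structured={structured_adherence!r} "
                f"text={extraction.adherence!r} (structured kept)"
            )

    for cat in RECOMMENDATION_CATEGORIES:
        col = cat.replace("recommendation_", "rec_")
        if extraction.recommendations[cat] and not merged.get(col, False):
            merged[col] = True
            provenance[col] = "nlp"

    merged["_provenance"] = provenance
    merged["_conflicts"] = conflicts
    return merged


class AlignmentError(KeyError):
    """Extraction results and ground truth disagree on patient-year keys."""


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float, bool]:
    undefined = (tp + fp) == 0
    precision = 0.0 if undefined else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    f1 = (
        0.0
        if precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    return precision, recall, f1, undefined


def evaluate_extraction(
    results: Mapping,
    truth: pd.DataFrame,
) -> pd.DataFrame:
    """Micro-averaged precision/recall/F1 per extraction category.

    ``results`` maps ``(patient_id, year)`` to :class:`ExtractionResult`;
    ``truth`` is the generator's ground-truth table with ``conditions``,
    ``drugs``, ``adherence`` and the four recommendation flags. Degenerate
    precision (no predictions at all) is reported as 0 with the
    ``undefined_precision`` flag set.
    """
    truth_keys = {(r.patient_id, r.year) for r in truth.itertuples()}
    missing = truth_keys - set(results)
    if missing:
        raise AlignmentError(
            f"extraction results missing for {len(missing)} patient-years, "
            f"e.g. {sorted(missing)[:5]}"
        )
    tallies = {
        cat: {"tp": 0, "fp": 0, "fn": 0}
        for cat in ("drugs", "conditions", "adherence", "recommendations")
    }
    for row in truth.itertuples():
        res = results[(row.patient_id, row.year)]
        for cat, true_set, pred_set in (
            ("drugs", set(row.drugs), res.drugs),
            ("conditions", set(row.conditions), res.conditions),
        ):
            tallies[cat]["tp"] += len(true_set & pred_set)
            tallies[cat]["fp"] += len(pred_set - true_set)
            tallies[cat]["fn"] += len(true_set - pred_set)
        true_adh, pred_adh = row.adherence, res.adherence
        if pred_adh != ADHERENCE_UNSTATED:
            if pred_adh == true_adh:
                tallies["adherence"]["tp"] += 1
            else:
                tallies["adherence"]["fp"] += 1
                if true_adh != ADHERENCE_UNSTATED:
                    tallies["adherence"]["fn"] += 1
        elif true_adh != ADHERENCE_UNSTATED:
            tallies["adherence"]["fn"] += 1
        for cat in RECOMMENDATION_CATEGORIES:
            true_flag = bool(getattr(row, cat.replace("recommendation_", "rec_")))
            pred_flag = res.recommendations[cat]
            if pred_flag and true_flag:
                tallies["recommendations"]["tp"] += 1
            elif pred_flag:
                tallies["recommendations"]["fp"] += 1
            elif true_flag:
                tallies["recommendations"]["fn"] += 1
    rows = []
    for cat, t in tallies.items():
        precision, recall, f1, undefined = _prf(t["tp"], t["fp"], t["fn"])
        rows.append(
            {
                "category": cat,
                "tp": t["tp"],
                "fp": t["fp"],
                "fn": t["fn"],
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "undefined_precision": undefined,
            }
        )
    return pd.DataFrame(rows).set_index("category")
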