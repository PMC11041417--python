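"""Symptom trigger lexicons and context cue lists.

Two plain-text, tab-separated files drive the whole extractor so that the
term lists stay auditable by clinicians:

``symptom_lexicon.tsv``
    columns ``symptom_id``, ``role``, ``phrase``; roles are ``trigger``,
    ``dvt_location``, ``dvt_feeling``, ``dvt_laterality``,
    ``pain_location`` and ``pain_term``.

``context_cues.tsv``
    columns ``cue_class``, ``phrase``; classes are ``negation``,
    ``uncertainty``, ``definite``, ``history``, ``non_patient``,
    ``generic_instruction``, ``checkbox_marker``, ``medication_indication``,
    ``present_report`` and ``scope_breaker``.

Two auxiliary files complete a lexicon directory: ``abbreviations.tsv``
(columns ``short``, ``long``) and ``spelling_words.txt`` (one word per
line, a supplement to the vocabulary implied by the lexicons themselves).

The shipped defaults are reconstructions assembled from published example
sentences and standard clinical usage; they are replaceable defaults, not
a recovered copy of any institution's term lists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .symptoms import DVT_SYMPTOMS, PAIN_SYMPTOMS, SYMPTOMS

Phrase = tuple[str, ...]

SYMPTOM_ROLES = (
    "trigger",
    "dvt_location",
    "dvt_feeling",
    "dvt_laterality",
    "pain_location",
    "pain_term",
)

CUE_CLASSES = (
    "negation",
    "uncertainty",
    "definite",
    "history",
    "non_patient",
    "generic_instruction",
    "checkbox_marker",
    "medication_indication",
    "present_report",
    "scope_breaker",
)

_PHRASE_CHARS = re.compile(r"^[a-z0-9 ]+$")


class LexiconError(ValueError):
    """Structured lexicon load/validation error naming file and line."""

    def __init__(self, message: str, path: str | Path | None = None,
                 line: int | None = None):
        self.path = str(path) if path is not None else None
        self.line = line
        where = ""
        if self.path is not None:
            where = f" [{self.path}" + (f":{line}" if line else "") + "]"
        super().__init__(message + where)


def normalize_phrase(phrase: str) -> Phrase:
    """Lowercase and single-space a phrase, returning its token tuple."""
    return tuple(phrase.lower().split())


@dataclass
class SymptomLexicon:
    """Trigger phrases and auxiliary term sets for one symptom.

    DVT symptoms carry location/feeling/laterality term sets for the
    composite co-occurrence rule; the two region-located pain symptoms
    carry location and pain term sets for the proximity rule, bounded by
    ``max_pain_distance`` (token-index difference, default 5).
    """

    symptom_id: str
    trigger_phrases: list[Phrase] = field(default_factory=list)
    dvt_location_terms: set[Phrase] = field(default_factory=set)
    dvt_feeling_terms: set[Phrase] = field(default_factory=set)
    dvt_laterality_terms: set[Phrase] = field(default_factory=set)
    pain_location_terms: set[Phrase] = field(default_factory=set)
    pain_terms: set[Phrase] = field(default_factory=set)
    max_pain_distance: int = 5

    def all_phrases(self) -> set[Phrase]:
        out: set[Phrase] = set(self.trigger_phrases)
        for s in (self.dvt_location_terms, self.dvt_feeling_terms,
                  self.dvt_laterality_terms, self.pain_location_terms,
                  self.pain_terms):
            out |= s
        return out


@dataclass
class ContextLexicon:
    """Context cue lists, abbreviation table and spelling vocabulary."""

    negation_terms: list[Phrase] = field(default_factory=list)
    uncertainty_terms: list[Phrase] = field(default_factory=list)
    definite_terms: list[Phrase] = field(default_factory=list)
    history_terms: list[Phrase] = field(default_factory=list)
    non_patient_terms: list[Phrase] = field(default_factory=list)
    generic_instruction_patterns: list[Phrase] = field(default_factory=list)
    checkbox_markers: list[Phrase] = field(default_factory=list)
    medication_indication_terms: list[Phrase] = field(default_factory=list)
    present_report_patterns: list[Phrase] = field(default_factory=list)
    scope_breakers: list[Phrase] = field(default_factory=list)
    abbreviation_table: dict[str, str] = field(default_factory=dict)
    spelling_dictionary: set[str] = field(default_factory=set)

    _CLASS_ATTR = {
        "negation": "negation_terms",
        "uncertainty": "uncertainty_terms",
        "definite": "definite_terms",
        "history": "history_terms",
        "non_patient": "non_patient_terms",
        "generic_instruction": "generic_instruction_patterns",
        "checkbox_marker": "checkbox_markers",
        "medication_indication": "medication_indication_terms",
        "present_report": "present_report_patterns",
        "scope_breaker": "scope_breakers",
    }

    def cue_list(self, cue_class: str) -> list[Phrase]:
        return getattr(self, self._CLASS_ATTR[cue_class])

    def without_cues(self) -> "ContextLexicon":
        """Copy with every cue list emptied (abbreviations/spelling kept)."""
        return replace(
            self,
            negation_terms=[], uncertainty_terms=[], definite_terms=[],
            history_terms=[], non_patient_terms=[],
            generic_instruction_patterns=[],
            medication_indication_terms=[], present_report_patterns=[],
            checkbox_markers=[("yes",)],  # invariant: non-empty
        )


# ---------------------------------------------------------------------------
# Loading

def _read_tsv(path: Path, n_cols: int, header: tuple[str, ...]):
    if not path.is_file():
        raise LexiconError("lexicon file not found", path)
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and tuple(p.strip() for p in parts) == header:
                continue
            if len(parts) != n_cols:
                raise LexiconError(
                    f"expected {n_cols} tab-separated columns, got "
                    f"{len(parts)}", path, lineno)
            rows.append((lineno, tuple(p.strip() for p in parts)))
    return rows


def _load_symptom_file(path: Path) -> dict[str, SymptomLexicon]:
    lexicons = {sid: SymptomLexicon(sid) for sid in SYMPTOMS}
    seen: dict[tuple[str, str], tuple[Phrase, int]] = {}
    for lineno, (sid, role, phrase) in _read_tsv(
            path, 3, ("symptom_id", "role", "phrase")):
        if sid not in lexicons:
            raise LexiconError(f"unknown symptom_id {sid!r}", path, lineno)
        if role not in SYMPTOM_ROLES:
            raise LexiconError(f"unknown role {role!r}", path, lineno)
        tokens = normalize_phrase(phrase)
        if not tokens:
            raise LexiconError("empty phrase", path, lineno)
        norm = " ".join(tokens)
        if not _PHRASE_CHARS.match(norm):
            raise LexiconError(
                f"phrase {phrase!r} contains characters outside "
                "letters/digits/space", path, lineno)
        key = (sid, norm)
        if key in seen:
            raise LexiconError(
                f"duplicate phrase {norm!r} for symptom {sid!r} "
                f"(first seen at line {seen[key][1]})", path, lineno)
        seen[key] = (tokens, lineno)
        lex = lexicons[sid]
        if role == "trigger":
            lex.trigger_phrases.append(tokens)
        elif role == "dvt_location":
            lex.dvt_location_terms.add(tokens)
        elif role == "dvt_feeling":
            lex.dvt_feeling_terms.add(tokens)
        elif role == "dvt_laterality":
            lex.dvt_laterality_terms.add(tokens)
        elif role == "pain_location":
            lex.pain_location_terms.add(tokens)
        elif role == "pain_term":
            lex.pain_terms.add(tokens)
    for sid in DVT_SYMPTOMS:
        lex = lexicons[sid]
        if not lex.dvt_location_terms or not lex.dvt_feeling_terms:
            raise LexiconError(
                f"{sid} requires non-empty dvt_location and dvt_feeling "
                "term sets", path)
    return lexicons


def _load_context_file(path: Path) -> ContextLexicon:
    ctx = ContextLexicon()
    for lineno, (cue_class, phrase) in _read_tsv(
            path, 2, ("cue_class", "phrase")):
        if cue_class not in CUE_CLASSES:
            raise LexiconError(f"unknown cue_class {cue_class!r}",
                               path, lineno)
        tokens = normalize_phrase(phrase)
        if not tokens:
            raise LexiconError("empty cue phrase", path, lineno)
        lst = ctx.cue_list(cue_class)
        if tokens in lst:
            raise LexiconError(
                f"duplicate {cue_class} cue {' '.join(tokens)!r}",
                path, lineno)
        lst.append(tokens)
    if not ctx.checkbox_markers:
        raise LexiconError("checkbox_marker list must be non-empty", path)
    return ctx


def _load_abbreviations(path: Path) -> dict[str, str]:
    table: dict[str, str] = {}
    for lineno, (short, long) in _read_tsv(path, 2, ("short", "long")):
        key = short.lower().strip()
        if not key:
            raise LexiconError("empty abbreviation", path, lineno)
        if key in table:
            raise LexiconError(f"duplicate abbreviation {key!r}",
                               path, lineno)
        table[key] = " ".join(long.lower().split())
    return table


def _load_words(path: Path) -> set[str]:
    if not path.is_file():
        raise LexiconError("lexicon file not found", path)
    words: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            w = raw.strip().lower()
            if w and not w.startswith("#"):
                words.add(w)
    return words


def build_spelling_dictionary(
        symptom_lexicons: Mapping[str, SymptomLexicon],
        ctx: ContextLexicon,
        extra_words: Iterable[str] = ()) -> set[str]:
    """Vocabulary for spell correction: every lexicon/cue token plus extras."""
    vocab: set[str] = set(extra_words)
    for lex in symptom_lexicons.values():
        for tokens in lex.all_phrases():
            vocab.update(tokens)
    for cue_class in CUE_CLASSES:
        for tokens in ctx.cue_list(cue_class):
            vocab.update(tokens)
    for long in ctx.abbreviation_table.values():
        vocab.update(long.split())
    return {w for w in vocab if w.isalpha()}


def load_lexicons(path: str | Path) -> tuple[dict[str, SymptomLexicon],
                                             ContextLexicon]:
    """Load a lexicon directory and return validated lexicons.

    ``path`` must be a directory containing ``symptom_lexicon.tsv`` and
    ``context_cues.tsv``; ``abbreviations.tsv`` and ``spelling_words.txt``
    are optional.
    """
    root = Path(path)
    if not root.is_dir():
        raise LexiconError("lexicon directory not found", root)
    lexicons = _load_symptom_file(root / "symptom_lexicon.tsv")
    ctx = _load_context_file(root / "context_cues.tsv")
    abbr = root / "abbreviations.tsv"
    if abbr.is_file():
        ctx.abbreviation_table = _load_abbreviations(abbr)
    words = root / "spelling_words.txt"
    extra = _load_words(words) if words.is_file() else set()
    ctx.spelling_dictionary = build_spelling_dictionary(lexicons, ctx, extra)
    return lexicons, ctx


def default_lexicon_dir() -> Path:
    return Path(str(resources.files("pdacsym").joinpath("data")))


def default_lexicons() -> tuple[dict[str, SymptomLexicon], ContextLexicon]:
    """Load the packaged default lexicons."""
    return load_lexicons(default_lexicon_dir())


# ---------------------------------------------------------------------------
# Writing (round-trip support)

def write_lexicons(symptom_lexicons: Mapping[str, SymptomLexicon],
                   ctx: ContextLexicon, path: str | Path) -> None:
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    with open(root / "symptom_lexicon.tsv", "w", encoding="utf-8") as fh:
        fh.write("symptom_id\trole\tphrase\n")
        for sid in SYMPTOMS:
            lex = symptom_lexicons.get(sid)
            if lex is None:
                continue
            rows = [("trigger", p) for p in lex.trigger_phrases]
            for role, terms in (
                    ("dvt_location", lex.dvt_location_terms),
                    ("dvt_feeling", lex.dvt_feeling_terms),
                    ("dvt_laterality", lex.dvt_laterality_terms),
                    ("pain_location", lex.pain_location_terms),
                    ("pain_term", lex.pain_terms)):
                rows.extend((role, p) for p in sorted(terms))
            for role, tokens in rows:
                fh.write(f"{sid}\t{role}\t{' '.join(tokens)}\n")
    with open(root / "context_cues.tsv", "w", encoding="utf-8") as fh:
        fh.write("cue_class\tphrase\n")
        for cue_class in CUE_CLASSES:
            for tokens in ctx.cue_list(cue_class):
                fh.write(f"{cue_class}\t{' '.join(tokens)}\n")
    with open(root / "abbreviations.tsv", "w", encoding="utf-8") as fh:
        fh.write("short\tlong\n")
        for short, long in ctx.abbreviation_table.items():
            fh.write(f"{short}\t{long}\n")
    with open(root / "spelling_words.txt", "w", encoding="utf-8") as fh:
        for w in sorted(ctx.spelling_dictionary):
            fh.write(w + "\n")


# ---------------------------------------------------------------------------
# Validation report

def validate_lexicons(symptom_lexicons: Mapping[str, SymptomLexicon],
                      ctx: ContextLexicon) -> dict[str, list[str]]:
    """Check every lexicon invariant; return ``{"violations": [...],
    "warnings": [...]}``.

    Report-only: loading already enforces the invariants, so a lexicon
    obtained from :func:`load_lexicons` yields an empty violation list.
    """
    violations: list[str] = []
    warnings: list[str] = []

    for sid, lex in symptom_lexicons.items():
        if sid not in SYMPTOMS:
            violations.append(f"unknown symptom_id {sid!r}")
        seen: set[Phrase] = set()
        for tokens in ([*lex.trigger_phrases]
                       + sorted(lex.dvt_location_terms)
                       + sorted(lex.dvt_feeling_terms)
                       + sorted(lex.dvt_laterality_terms)
                       + sorted(lex.pain_location_terms)
                       + sorted(lex.pain_terms)):
            joined = " ".join(tokens)
            if not tokens:
                violations.append(f"{sid}: empty phrase")
                continue
            if joined != joined.lower() or not _PHRASE_CHARS.match(joined):
                violations.append(
                    f"{sid}: phrase {joined!r} not lowercase "
                    "letters/digits/space")
            if tokens in seen:
                violations.append(f"{sid}: duplicate phrase {joined!r}")
            seen.add(tokens)
        if sid in DVT_SYMPTOMS:
            if not lex.dvt_location_terms:
                violations.append(f"{sid}: empty dvt_location set")
            if not lex.dvt_feeling_terms:
                violations.append(f"{sid}: empty dvt_feeling set")
        if lex.max_pain_distance < 1:
            violations.append(f"{sid}: max_pain_distance < 1")

    ids = sorted(symptom_lexicons)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            shared = (set(symptom_lexicons[a].trigger_phrases)
                      & set(symptom_lexicons[b].trigger_phrases))
            for tokens in sorted(shared):
                warnings.append(
                    f"phrase {' '.join(tokens)!r} listed under both "
                    f"{a} and {b}")

    for cue_class in CUE_CLASSES:
        for tokens in ctx.cue_list(cue_class):
            joined = " ".join(tokens)
            if joined != joined.lower():
                violations.append(
                    f"{cue_class} cue {joined!r} not lowercase")
    if not ctx.checkbox_markers:
        violations.append("checkbox_marker list is empty")
    shorts = list(ctx.abbreviation_table)
    if len(shorts) != len(set(shorts)):
        violations.append("duplicate abbreviation keys")
    return {"violations": violations, "warnings": warnings}
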