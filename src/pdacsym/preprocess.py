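"""Note filtering, text normalization, sentence splitting and tokenization.

The preprocessing contract mirrors how clinical notes are prepared for
rule-based extraction: lowercase conversion; removal of every character
that is not a letter, digit, space, period, comma, question mark, colon
or semicolon; sentence splitting on periods, question marks, semicolons
and line breaks (with protection for decimal numbers); whitespace
tokenization; expansion of abbreviated words; and dictionary-based
correction of misspelled words.

Character offsets are 0-based half-open against the raw note text, so a
token's provenance can always be sliced back out of the original note.
Note the whitelist's side effect: deleted characters join their
neighbours, e.g. ``c/o`` becomes ``co`` and ``daughter-in-law`` becomes
``daughterinlaw``; the shipped abbreviation table and cue lists carry the
joined forms.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from .lexicon import ContextLexicon

logger = logging.getLogger(__name__)

_LETTERS_DIGITS = "abcdefghijklmnopqrstuvwxyz0123456789"
_KEPT_PUNCT = ".,?:;"
_SENTENCE_BREAKS = ".?;\n"


@dataclass
class RawNote:
    """One clinical note (or patient message) with its metadata."""

    note_id: str
    patient_id: str = ""
    group: str = "unknown"  # case | control | unknown
    note_date: dt.date | None = None
    encounter_type: str = ""
    note_type: str = ""
    department: str = ""
    text: str = ""


@dataclass
class Token:
    form: str                 # normalized (possibly expanded/corrected)
    start: int                # raw-text char offset, 0-based
    end: int                  # half-open
    pre_punct: str = ""       # retained punctuation since previous token
    altered: bool = False     # abbreviation-expanded or spell-corrected


@dataclass
class Sentence:
    index: int
    start: int
    end: int
    text: str                 # normalized sentence text
    tokens: list[Token] = field(default_factory=list)

    @property
    def forms(self) -> list[str]:
        return [t.form for t in self.tokens]


@dataclass
class ProcessedNote:
    note_id: str
    sentences: list[Sentence] = field(default_factory=list)
    steps: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Note filtering

@dataclass
class NoteExclusions:
    """Metadata-based note exclusion lists (notes unlikely to carry
    symptoms: e.g. surgery encounters, patient-instruction or anesthesia
    note types, health-education departments)."""

    encounter_types: set[str] = field(default_factory=set)
    note_types: set[str] = field(default_factory=set)
    departments: set[str] = field(default_factory=set)

    @classmethod
    def default(cls) -> "NoteExclusions":
        return cls(
            encounter_types={"surgery"},
            note_types={"patient instructions", "anesthesia"},
            departments={"health education"},
        )

    @classmethod
    def none(cls) -> "NoteExclusions":
        return cls()


def filter_notes(notes: Iterable[RawNote],
                 exclusions: NoteExclusions | None = None,
                 ) -> tuple[list[RawNote], dict[str, int]]:
    """Drop notes whose metadata matches an exclusion list.

    Returns the eligible notes unchanged plus a per-reason exclusion
    tally.  Unknown metadata values pass through; nothing is excluded
    silently.
    """
    excl = exclusions if exclusions is not None else NoteExclusions.default()
    enc = {v.strip().lower() for v in excl.encounter_types}
    typ = {v.strip().lower() for v in excl.note_types}
    dep = {v.strip().lower() for v in excl.departments}
    eligible: list[RawNote] = []
    tally = {"encounter_type": 0, "note_type": 0, "department": 0}
    for note in notes:
        if note.encounter_type.strip().lower() in enc:
            tally["encounter_type"] += 1
        elif note.note_type.strip().lower() in typ:
            tally["note_type"] += 1
        elif note.department.strip().lower() in dep:
            tally["department"] += 1
        else:
            eligible.append(note)
    return eligible, tally


# ---------------------------------------------------------------------------
# Normalization

def _fragment_len(text: str, i: int, step: int) -> int:
    """Length of the alphanumeric run adjacent to position ``i``."""
    n = 0
    j = i + step
    while 0 <= j < len(text) and text[j].lower() in _LETTERS_DIGITS:
        n += 1
        j += step
    return n


def normalize_text(text: str) -> tuple[str, list[int]]:
    """Lowercase and whitelist-filter ``text``.

    Returns ``(normalized, offsets)`` where ``offsets[i]`` is the index in
    ``text`` of the character that produced ``normalized[i]``.  Retained
    characters are ASCII letters and digits, space and ``. , ? : ;``;
    whitespace runs collapse to one space; everything else is deleted,
    joining its neighbours.  Exception: a slash or hyphen flanked by
    word fragments of two or more characters separates them instead
    ("vomiting/nausea" and "daughter-in-law" keep their words, while
    abbreviation shorthand like "c/o" fuses to "co").  Idempotent.
    """
    out: list[str] = []
    offsets: list[int] = []
    space_at: int | None = None
    for i, ch in enumerate(text):
        cl = ch.lower()
        separates = (cl in "/-"
                     and _fragment_len(text, i, -1) >= 2
                     and _fragment_len(text, i, +1) >= 2)
        if cl.isspace() or separates:
            if out and space_at is None:
                space_at = i
        elif cl in _LETTERS_DIGITS or cl in _KEPT_PUNCT:
            if space_at is not None:
                out.append(" ")
                offsets.append(space_at)
                space_at = None
            out.append(cl)
            offsets.append(i)
        # other characters are removed
    return "".join(out), offsets


# ---------------------------------------------------------------------------
# Abbreviations and spelling

def expand_abbreviations(tokens: Sequence[Token],
                         table: Mapping[str, str]) -> list[Token]:
    """Replace each token matching a short form by its (possibly
    multi-token) expansion; every expansion token keeps the source span."""
    out: list[Token] = []
    for tok in tokens:
        expansion = table.get(tok.form)
        if expansion is None:
            out.append(tok)
            continue
        parts = expansion.split()
        for j, part in enumerate(parts):
            out.append(Token(form=part, start=tok.start, end=tok.end,
                             pre_punct=tok.pre_punct if j == 0 else "",
                             altered=True))
    return out


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def correct_spelling(token: str, dictionary: set[str],
                     max_distance: int = 1) -> str:
    """Correct an out-of-dictionary token to its unique nearest
    dictionary word within ``max_distance`` edits; otherwise return the
    token unchanged (ties are left unchanged and logged)."""
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    if not dictionary or token in dictionary or max_distance == 0:
        return token
    best: list[str] = []
    best_d = max_distance + 1
    for word in dictionary:
        if abs(len(word) - len(token)) > max_distance:
            continue
        res = edlib.align(token, word, task="distance", k=max_distance)
        d = res["editDistance"]
        if d < 0:
            continue
        if d < best_d:
            best, best_d = [word], d
        elif d == best_d:
            best.append(word)
    if len(best) == 1:
        return best[0]
    if len(best) > 1:
        logger.debug("spelling tie for %r: %s", token, sorted(best))
    return token


# ---------------------------------------------------------------------------
# Sentence splitting and tokenization

def _sentence_spans(text: str) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    start = 0
    for i, ch in enumerate(text):
        if ch not in _SENTENCE_BREAKS:
            continue
        if (ch == "." and 0 < i < len(text) - 1
                and text[i - 1].isdigit() and text[i + 1].isdigit()):
            continue  # decimal number, not a boundary
        spans.append((start, i))
        start = i + 1
    spans.append((start, len(text)))
    return spans


def _tokenize_sentence(norm: str, offsets: list[int],
                       index: int, start: int, end: int) -> Sentence:
    tokens: list[Token] = []
    gap = ""
    i = 0
    cur: list[int] | None = None  # [first_norm_idx, last_norm_idx]
    for i, ch in enumerate(norm):
        if ch in _LETTERS_DIGITS:
            if cur is None:
                cur = [i, i]
            else:
                cur[1] = i
        else:
            if cur is not None:
                tokens.append(Token(
                    form=norm[cur[0]:cur[1] + 1],
                    start=offsets[cur[0]], end=offsets[cur[1]] + 1,
                    pre_punct=gap))
                gap = ""
                cur = None
            if ch in _KEPT_PUNCT:
                gap += ch
    if cur is not None:
        tokens.append(Token(form=norm[cur[0]:cur[1] + 1],
                            start=offsets[cur[0]], end=offsets[cur[1]] + 1,
                            pre_punct=gap))
    return Sentence(index=index, start=start, end=end, text=norm,
                    tokens=tokens)


def split_and_tokenize(note: RawNote, ctx: ContextLexicon | None = None,
                       spell_max_distance: int = 1,
                       spell_min_length: int = 4) -> ProcessedNote:
    """Full preprocessing of one note into a :class:`ProcessedNote`.

    Sentences are split on period/question mark/semicolon/newline with
    decimal protection; each sentence is normalized and tokenized, then
    abbreviations are expanded and, last, out-of-dictionary tokens of at
    least ``spell_min_length`` letters are spell-corrected (expansion runs
    first so short forms are never "corrected").
    """
    steps = ["normalize", "sentence_split", "tokenize"]
    sentences: list[Sentence] = []
    for s, e in _sentence_spans(note.text):
        raw = note.text[s:e]
        norm, offsets = normalize_text(raw)
        if not any(c in _LETTERS_DIGITS for c in norm):
            continue
        offsets = [o + s for o in offsets]
        sent = _tokenize_sentence(norm, offsets, len(sentences), s, e)
        sentences.append(sent)
    if ctx is not None and ctx.abbreviation_table:
        steps.append("expand_abbreviations")
        for sent in sentences:
            sent.tokens = expand_abbreviations(sent.tokens,
                                               ctx.abbreviation_table)
    if ctx is not None and ctx.spelling_dictionary and spell_max_distance > 0:
        steps.append("correct_spelling")
        for sent in sentences:
            for tok in sent.tokens:
                if (not tok.altered and tok.form.isalpha()
                        and len(tok.form) >= spell_min_length
                        and tok.form not in ctx.spelling_dictionary):
                    fixed = correct_spelling(tok.form,
                                             ctx.spelling_dictionary,
                                             spell_max_distance)
                    if fixed != tok.form:
                        tok.form = fixed
                        tok.altered = True
    return ProcessedNote(note_id=note.note_id, sentences=sentences,
                         steps=steps)
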