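"""Sentence-level sectionization of clinical notes.

Several classification rules key on the note section a sentence sits in
(chief complaint, diagnosis, history of present illness, family history,
instructions, ...).  Structured EHR section metadata is assumed
unavailable, so headers are detected from the text itself: a sentence
whose leading tokens match a header phrase opens a section that runs
until the next header or the end of the note.  A one-word header
("diagnosis", "medications") must be followed by a colon or stand alone
as its own sentence; multi-word headers ("chief complaint", "primary
encounter diagnosis") are unambiguous enough to open a section with
in-sentence content and no colon.  The header and any content in the
same sentence share the section label; sentences before any header are
``other``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .lexicon import LexiconError, Phrase, _read_tsv, normalize_phrase
from .preprocess import ProcessedNote, Sentence

SECTION_LABELS = (
    "chief_complaint",
    "diagnosis",
    "symptom_list",
    "history_present_illness",
    "past_medical_history",
    "family_history",
    "instructions",
    "medications",
    "review_of_systems",
    "other",
)

#: Sections whose mentions count as affirmed (DVT excepted for diagnosis).
YES_SECTIONS = frozenset({
    "chief_complaint", "diagnosis", "symptom_list",
    "history_present_illness",
})

HeaderPatterns = dict[str, list[Phrase]]


@dataclass(frozen=True)
class SectionSpan:
    label: str
    start: int  # sentence index, inclusive
    end: int    # sentence index, exclusive


def load_header_patterns(path: str | Path) -> HeaderPatterns:
    patterns: HeaderPatterns = {}
    for lineno, (label, phrase) in _read_tsv(
            Path(path), 2, ("label", "phrase")):
        if label not in SECTION_LABELS or label == "other":
            raise LexiconError(f"unknown section label {label!r}",
                               path, lineno)
        tokens = normalize_phrase(phrase)
        if not tokens:
            raise LexiconError("empty header phrase", path, lineno)
        patterns.setdefault(label, []).append(tokens)
    return patterns


def default_header_patterns() -> HeaderPatterns:
    path = resources.files("pdacsym").joinpath("data/section_headers.tsv")
    return load_header_patterns(str(path))


def header_prefix(sentence: Sentence,
                  patterns: HeaderPatterns) -> tuple[str, int] | None:
    """Longest header phrase opening ``sentence``, as ``(label, n_tokens)``.

    Returns None when the sentence does not open a section.  One-token
    headers require a following colon or the header alone as the whole
    sentence.
    """
    forms = sentence.forms
    best: tuple[str, int] | None = None
    for label, phrases in patterns.items():
        for phrase in phrases:
            n = len(phrase)
            if n > len(forms) or tuple(forms[:n]) != phrase:
                continue
            colon = (n < len(forms)
                     and ":" in sentence.tokens[n].pre_punct)
            alone = n == len(forms)
            if n == 1 and not (colon or alone):
                continue
            if best is None or n > best[1]:
                best = (label, n)
    return best


def label_sections(note: ProcessedNote,
                   patterns: HeaderPatterns | None = None,
                   ) -> list[SectionSpan]:
    """Partition the note's sentences into labeled section spans."""
    if patterns is None:
        patterns = default_header_patterns()
    labels: list[str] = []
    current = "other"
    for sent in note.sentences:
        hit = header_prefix(sent, patterns)
        if hit is not None:
            current = hit[0]
        labels.append(current)
    spans: list[SectionSpan] = []
    for i, label in enumerate(labels):
        if spans and spans[-1].label == label:
            spans[-1] = SectionSpan(label, spans[-1].start, i + 1)
        else:
            spans.append(SectionSpan(label, i, i + 1))
    return spans


def sentence_labels(note: ProcessedNote,
                    patterns: HeaderPatterns | None = None) -> list[str]:
    """Per-sentence section label (flat view over :func:`label_sections`)."""
    labels = ["other"] * len(note.sentences)
    for span in label_sections(note, patterns):
        for i in range(span.start, span.end):
            labels[i] = span.label
    return labels
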