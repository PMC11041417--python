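"""Sentence-level yes/no decisions per symptom and note-level aggregation.

A sentence is judged per symptom from its mentions and their context
flags.  Every exclusion dominates every inclusion within a mention: a
mention that is generic/conditional, about another person, historical,
negated, uncertain, a bare checklist term, or medication-treated during
hospitalization is "no" regardless of any affirming evidence attached to
it.  A surviving mention is "yes" when it is checkbox-affirmed, sits in
an affirming section (diagnosis — except DVT —, chief complaint, symptom
list, history of present illness), is medication-treated outside
hospitalization, carries a definite cue, or is an unflagged
present-tense report.  Otherwise the sentence contributes "no" with
reason ``NO_INSUFFICIENT_EVIDENCE``.

A note is positive for a symptom iff at least one sentence decided
"yes"; nausea/vomiting is additionally forced negative for
hospitalization encounters (emergency visits excepted), with the
exclusion recorded on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .context import (DEFAULT_HOSPITAL_ENCOUNTERS, ContextFlags,
                      compute_flags)
from .lexicon import (ContextLexicon, Phrase, SymptomLexicon,
                      default_lexicons)
from .matcher import Mention, find_mentions
from .preprocess import (NoteExclusions, ProcessedNote, RawNote,
                         Sentence, filter_notes, split_and_tokenize)
from .sections import (HeaderPatterns, YES_SECTIONS,
                       default_header_patterns, sentence_labels)
from .symptoms import DVT_SYMPTOMS, SYMPTOMS

logger = logging.getLogger(__name__)

# Stable reason codes, exclusions first (their order is the precedence
# order used to report why a sentence was suppressed).
NO_REASONS = (
    "NO_GENERIC_CONDITIONAL",
    "NO_NON_PATIENT",
    "NO_HISTORICAL",
    "NO_NEGATED",
    "NO_UNCERTAIN",
    "NO_BARE_TERM",
    "NO_MEDICATION_HOSPITAL",
)
YES_REASONS = (
    "YES_CHECKBOX",
    "YES_SECTION_DIAGNOSIS",
    "YES_SECTION_CHIEF_COMPLAINT",
    "YES_SECTION_SYMPTOM_LIST",
    "YES_SECTION_HPI",
    "YES_MEDICATION_OUTPATIENT",
    "YES_DEFINITE",
    "YES_PRESENT_REPORT",
)
REASON_CODES = NO_REASONS + YES_REASONS + ("NO_INSUFFICIENT_EVIDENCE",)

_SECTION_REASON = {
    "diagnosis": "YES_SECTION_DIAGNOSIS",
    "chief_complaint": "YES_SECTION_CHIEF_COMPLAINT",
    "symptom_list": "YES_SECTION_SYMPTOM_LIST",
    "history_present_illness": "YES_SECTION_HPI",
}


@dataclass
class PipelineConfig:
    """Rule toggles and thresholds, all defaulting to the documented
    behaviour of the extraction rules."""

    require_laterality: bool = False
    max_pain_distance: int = 5
    radiation_window: int = 3
    checkbox_overrides_negation: bool = False
    historical_year_threshold: int = 1
    hospital_encounter_types: frozenset[str] = DEFAULT_HOSPITAL_ENCOUNTERS
    yes_sections: frozenset[str] = YES_SECTIONS
    spell_max_distance: int = 1
    spell_min_length: int = 4
    exclusions: NoteExclusions = field(
        default_factory=NoteExclusions.default)
    strict: bool = False


@dataclass
class SentenceDecision:
    sentence_index: int
    symptom_id: str
    decision: str                    # yes | no
    reason_code: str
    mention: Mention | None = None
    section_label: str = "other"
    evidence_text: str = ""


@dataclass
class NoteResult:
    note_id: str
    symptoms: dict[str, bool]
    decisions: list[SentenceDecision] = field(default_factory=list)
    exclusions: list[str] = field(default_factory=list)


def _no_reason(flags: ContextFlags) -> str | None:
    checks = (
        ("NO_GENERIC_CONDITIONAL", flags.generic_conditional),
        ("NO_NON_PATIENT", flags.non_patient),
        ("NO_HISTORICAL", flags.historical),
        ("NO_NEGATED", flags.negated),
        ("NO_UNCERTAIN", flags.uncertain),
        ("NO_BARE_TERM", flags.bare_term),
        ("NO_MEDICATION_HOSPITAL", flags.medication_in_hospital),
    )
    for code, hit in checks:
        if hit:
            return code
    return None


def _yes_reason(flags: ContextFlags, symptom_id: str, section: str,
                config: PipelineConfig) -> str | None:
    if flags.checkbox_affirmed:
        return "YES_CHECKBOX"
    if section in config.yes_sections and not (
            section == "diagnosis" and symptom_id in DVT_SYMPTOMS):
        return _SECTION_REASON[section]
    if flags.medication_treated and not flags.medication_in_hospital:
        return "YES_MEDICATION_OUTPATIENT"
    if flags.definite:
        return "YES_DEFINITE"
    if flags.present_report:
        return "YES_PRESENT_REPORT"
    return None


def classify_sentence(sentence: Sentence | Sequence[str],
                      annotated: Sequence[tuple[Mention, ContextFlags]],
                      section: str = "other",
                      config: PipelineConfig | None = None,
                      ) -> list[SentenceDecision]:
    """One decision per symptom with at least one mention.

    Symptoms without mentions are absent from the list (implicit no).
    """
    config = config or PipelineConfig()
    text = sentence.text if isinstance(sentence, Sentence) else " ".join(
        sentence)
    index = sentence.index if isinstance(sentence, Sentence) else 0
    by_symptom: dict[str, list[tuple[Mention, ContextFlags]]] = {}
    for mention, flags in annotated:
        by_symptom.setdefault(mention.symptom_id, []).append(
            (mention, flags))
    decisions: list[SentenceDecision] = []
    for sid in sorted(by_symptom):
        pairs = sorted(by_symptom[sid], key=lambda p: p[0].start)
        yes: tuple[Mention, str] | None = None
        blocked: tuple[Mention, str] | None = None
        for mention, flags in pairs:
            skip_no = (config.checkbox_overrides_negation
                       and flags.checkbox_affirmed
                       and section == "symptom_list")
            no = None if skip_no else _no_reason(flags)
            if no is not None:
                if blocked is None:
                    blocked = (mention, no)
                continue
            reason = _yes_reason(flags, sid, section, config)
            if reason is not None and yes is None:
                yes = (mention, reason)
        if yes is not None:
            mention, reason = yes
            decisions.append(SentenceDecision(
                index, sid, "yes", reason, mention, section, text))
        else:
            mention, reason = blocked if blocked is not None else (
                pairs[0][0], "NO_INSUFFICIENT_EVIDENCE")
            decisions.append(SentenceDecision(
                index, sid, "no", reason, mention, section, text))
    return decisions


def aggregate_note(decisions: Iterable[SentenceDecision], note: RawNote,
                   config: PipelineConfig | None = None) -> NoteResult:
    """Note-level OR over sentence decisions, plus the encounter-based
    nausea/vomiting exclusion for hospitalization notes."""
    config = config or PipelineConfig()
    decisions = list(decisions)
    symptoms = {sid: False for sid in SYMPTOMS}
    for d in decisions:
        if d.decision == "yes":
            symptoms[d.symptom_id] = True
    exclusions: list[str] = []
    if (note.encounter_type.strip().lower()
            in config.hospital_encounter_types):
        if symptoms["nausea_vomiting"]:
            exclusions.append("nausea_vomiting_hospital_encounter")
        symptoms["nausea_vomiting"] = False
    return NoteResult(note_id=note.note_id, symptoms=symptoms,
                      decisions=decisions, exclusions=exclusions)


# ---------------------------------------------------------------------------
# End-to-end pipeline

@dataclass
class RunSummary:
    n_input: int = 0
    n_eligible: int = 0
    n_failed: int = 0
    excluded: dict[str, int] = field(default_factory=dict)
    symptom_counts: dict[str, int] = field(default_factory=dict)
    n_notes_any_symptom: int = 0

    def frame(self) -> pd.DataFrame:
        """Per-symptom counts and percentages over processed notes."""
        n = max(self.n_eligible - self.n_failed, 1)
        rows = [{"symptom_id": sid,
                 "n_notes": self.symptom_counts.get(sid, 0),
                 "percent": round(100.0 * self.symptom_counts.get(sid, 0)
                                  / n, 2)}
                for sid in SYMPTOMS]
        return pd.DataFrame(rows)


def classify_note(note: RawNote,
                  symptom_lexicons: Mapping[str, SymptomLexicon],
                  ctx: ContextLexicon,
                  config: PipelineConfig | None = None,
                  header_patterns: HeaderPatterns | None = None,
                  ) -> NoteResult:
    """Preprocess, sectionize, match, contextualize and classify one note."""
    config = config or PipelineConfig()
    if header_patterns is None:
        header_patterns = default_header_patterns()
    header_phrases: list[Phrase] = [p for ps in header_patterns.values()
                                    for p in ps]
    if config.max_pain_distance != 5:
        symptom_lexicons = {
            sid: replace(lex, max_pain_distance=config.max_pain_distance)
            for sid, lex in symptom_lexicons.items()}
    processed: ProcessedNote = split_and_tokenize(
        note, ctx, config.spell_max_distance, config.spell_min_length)
    labels = sentence_labels(processed, header_patterns)
    decisions: list[SentenceDecision] = []
    for sent, label in zip(processed.sentences, labels):
        mentions = find_mentions(
            sent, symptom_lexicons,
            require_laterality=config.require_laterality,
            radiation_window=config.radiation_window,
            sentence_index=sent.index)
        annotated = [
            (m, compute_flags(
                sent, m, ctx, section=label, note_date=note.note_date,
                encounter_type=note.encounter_type,
                hospital_encounters=config.hospital_encounter_types,
                year_threshold=config.historical_year_threshold,
                header_phrases=header_phrases))
            for m in mentions]
        decisions.extend(
            classify_sentence(sent, annotated, label, config))
    return aggregate_note(decisions, note, config)


def run_pipeline(notes: Iterable[RawNote],
                 lexicons: tuple[Mapping[str, SymptomLexicon],
                                 ContextLexicon] | None = None,
                 config: PipelineConfig | None = None,
                 header_patterns: HeaderPatterns | None = None,
                 ) -> tuple[list[NoteResult], RunSummary]:
    """Deterministic end-to-end run: filter, preprocess, sectionize,
    match, contextualize, classify, aggregate."""
    config = config or PipelineConfig()
    if lexicons is None:
        lexicons = default_lexicons()
    symptom_lexicons, ctx = lexicons
    notes = list(notes)
    eligible, tally = filter_notes(notes, config.exclusions)
    summary = RunSummary(n_input=len(notes), n_eligible=len(eligible),
                         excluded=tally,
                         symptom_counts={sid: 0 for sid in SYMPTOMS})
    results: list[NoteResult] = []
    for note in eligible:
        try:
            result = classify_note(note, symptom_lexicons, ctx, config,
                                   header_patterns)
        except Exception:
            if config.strict:
                raise
            summary.n_failed += 1
            logger.exception("skipping malformed note %r", note.note_id)
            continue
        results.append(result)
        if any(result.symptoms.values()):
            summary.n_notes_any_symptom += 1
        for sid, present in result.symptoms.items():
            if present:
                summary.symptom_counts[sid] += 1
    return results, summary


def results_to_frame(results: Iterable[NoteResult]) -> pd.DataFrame:
    """Note-by-symptom boolean matrix (index note_id, one column per
    symptom, canonical order)."""
    rows = {r.note_id: [bool(r.symptoms.get(sid, False))
                        for sid in SYMPTOMS] for r in results}
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(SYMPTOMS))
    frame.index.name = "note_id"
    return frame
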