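"""Contextual modifier detection for symptom mentions.

Each detector answers one question about a mention — is it negated,
uncertain, definite, historical, about somebody other than the patient,
part of a generic instruction, medication-treated, checkbox-affirmed —
and is a pure function of the sentence, the mention, the cue lists and
note metadata.  Flags never suppress each other here; precedence among
them is applied only in the classifier, so every rule stays unit-testable
in isolation.

Scope model: a cue governs triggers in its own *clause*.  Clauses are
delimited by adversative scope breakers ("but", "however"), and by a
colon when the text before the colon is a section header ("history of
present illness: ..."), so header words never masquerade as cues for the
content that follows them.  Negation/uncertainty/definite cues look
forward only, which also yields list distribution: "denies A, B, C"
negates all three listed triggers.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass
from typing import Sequence

from .lexicon import ContextLexicon, Phrase
from .matcher import Mention, phrase_occurrences
from .preprocess import Sentence

logger = logging.getLogger(__name__)

_YEAR = re.compile(r"^(19|20)\d\d$")

DEFAULT_HOSPITAL_ENCOUNTERS = frozenset(
    {"hospital", "inpatient", "hospitalization"})


@dataclass
class ContextFlags:
    negated: bool = False
    uncertain: bool = False
    definite: bool = False
    historical: bool = False
    non_patient: bool = False
    generic_conditional: bool = False
    medication_treated: bool = False
    medication_in_hospital: bool = False
    checkbox_affirmed: bool = False
    present_report: bool = False
    bare_term: bool = False


def _forms_gaps(sentence: Sequence[str] | Sentence
                ) -> tuple[list[str], list[str]]:
    if isinstance(sentence, Sentence):
        return sentence.forms, [t.pre_punct for t in sentence.tokens]
    forms = list(sentence)
    return forms, [""] * len(forms)


def _cue_occurrences(forms: Sequence[str],
                     cues: list[Phrase]) -> list[tuple[int, int]]:
    occs: list[tuple[int, int]] = []
    for cue in cues:
        occs.extend(phrase_occurrences(forms, cue))
    return sorted(set(occs))


def segment_clauses(sentence: Sequence[str] | Sentence,
                    ctx: ContextLexicon,
                    header_phrases: Sequence[Phrase] = ()) -> list[int]:
    """Clause id per token.

    Boundaries open before a scope-breaker token, after a sentence-initial
    multi-word section header, and after a colon whose preceding tokens
    end with a section header phrase.
    """
    forms, gaps = _forms_gaps(sentence)
    n = len(forms)
    boundaries: set[int] = set()
    for s, _ in _cue_occurrences(forms, ctx.scope_breakers):
        boundaries.add(s)
    for hp in header_phrases:
        k = len(hp)
        if k >= 2 and k <= n and tuple(forms[:k]) == hp:
            boundaries.add(k)
    for i in range(1, n):
        if ":" not in gaps[i]:
            continue
        for hp in header_phrases:
            k = len(hp)
            if i >= k and tuple(forms[i - k:i]) == hp:
                boundaries.add(i)
                break
    ids: list[int] = []
    cur = 0
    for i in range(n):
        if i in boundaries:
            cur += 1
        ids.append(cur)
    return ids


def _forward_cue(sentence: Sequence[str] | Sentence, mention: Mention,
                 ctx: ContextLexicon, cues: list[Phrase],
                 header_phrases: Sequence[Phrase] = ()) -> bool:
    """True iff a cue ends before the trigger within the same clause."""
    forms, _ = _forms_gaps(sentence)
    clause = segment_clauses(sentence, ctx, header_phrases)
    t = mention.start
    for s, e in _cue_occurrences(forms, cues):
        if e <= t and clause[s] == clause[t]:
            return True
    return False


def _clause_cue(sentence: Sequence[str] | Sentence, mention: Mention,
                ctx: ContextLexicon, cues: list[Phrase],
                header_phrases: Sequence[Phrase] = ()) -> bool:
    """True iff a cue occurs anywhere in the trigger's clause."""
    forms, _ = _forms_gaps(sentence)
    clause = segment_clauses(sentence, ctx, header_phrases)
    t = mention.start
    for s, _e in _cue_occurrences(forms, cues):
        if clause[s] == clause[t]:
            return True
    return False


def detect_negation(sentence, mention: Mention, ctx: ContextLexicon,
                    header_phrases: Sequence[Phrase] = ()) -> bool:
    return _forward_cue(sentence, mention, ctx, ctx.negation_terms,
                        header_phrases)


def detect_uncertainty(sentence, mention: Mention, ctx: ContextLexicon,
                       header_phrases: Sequence[Phrase] = ()) -> bool:
    return _forward_cue(sentence, mention, ctx, ctx.uncertainty_terms,
                        header_phrases)


def detect_definite(sentence, mention: Mention, ctx: ContextLexicon,
                    header_phrases: Sequence[Phrase] = ()) -> bool:
    return _forward_cue(sentence, mention, ctx, ctx.definite_terms,
                        header_phrases)


def detect_present_report(sentence, mention: Mention, ctx: ContextLexicon,
                          header_phrases: Sequence[Phrase] = ()) -> bool:
    """First/second-person or present-tense report pattern preceding the
    trigger (the operational reading of "present at the time of visit")."""
    return _forward_cue(sentence, mention, ctx,
                        ctx.present_report_patterns, header_phrases)


def detect_historical(sentence, mention: Mention, ctx: ContextLexicon,
                      note_date: dt.date | None = None,
                      year_threshold: int = 1,
                      header_phrases: Sequence[Phrase] = ()) -> bool:
    """History cue in the trigger's clause, or an explicit calendar year
    at least ``year_threshold`` years before the note date.

    A year immediately preceded by "since" marks symptom onset, not
    historicity ("55 lb weight loss since march 2009" is current).
    """
    if _clause_cue(sentence, mention, ctx, ctx.history_terms,
                   header_phrases):
        return True
    forms, _ = _forms_gaps(sentence)
    clause = segment_clauses(sentence, ctx, header_phrases)
    t = mention.start
    for i, form in enumerate(forms):
        if not _YEAR.match(form) or clause[i] != clause[t]:
            continue
        if note_date is None:
            logger.debug("year token %r but no note date; not historical",
                         form)
            continue
        if any(forms[j] == "since" for j in range(max(0, i - 2), i)):
            continue
        if note_date.year - int(form) >= year_threshold:
            return True
    return False


def detect_non_patient(sentence, mention: Mention, ctx: ContextLexicon,
                       section: str = "other",
                       header_phrases: Sequence[Phrase] = ()) -> bool:
    if section == "family_history":
        return True
    return _forward_cue(sentence, mention, ctx, ctx.non_patient_terms,
                        header_phrases)


def detect_generic_conditional(sentence, mention: Mention,
                               ctx: ContextLexicon,
                               header_phrases: Sequence[Phrase] = ()) -> bool:
    return _clause_cue(sentence, mention, ctx,
                       ctx.generic_instruction_patterns, header_phrases)


def detect_checkbox(sentence, mention: Mention, ctx: ContextLexicon,
                    section: str = "other") -> bool:
    """Trigger followed within two tokens by a checkbox marker, or
    immediately preceded by one inside a symptom-list section."""
    forms, _ = _forms_gaps(sentence)
    markers = {cue[0] for cue in ctx.checkbox_markers if len(cue) == 1}
    end = mention.end
    for j in (end, end + 1):
        if j < len(forms) and forms[j] in markers:
            return True
    if section == "symptom_list":
        j = mention.start - 1
        if j >= 0 and forms[j] in markers:
            return True
    return False


def detect_bare_term(sentence, mention: Mention) -> bool:
    forms, _ = _forms_gaps(sentence)
    return mention.token_count == len(forms)


def detect_medication_treatment(
        sentence, mention: Mention, ctx: ContextLexicon,
        encounter_type: str = "",
        hospital_encounters: frozenset[str] = DEFAULT_HOSPITAL_ENCOUNTERS,
        header_phrases: Sequence[Phrase] = ()) -> tuple[bool, bool]:
    """(medication_treated, medication_in_hospital).

    A medication-indication cue preceding the trigger marks it treated;
    the hospital variant additionally requires a hospitalization
    encounter (emergency visits are not in the hospital set).
    """
    treated = _forward_cue(sentence, mention, ctx,
                           ctx.medication_indication_terms, header_phrases)
    in_hospital = (treated and
                   encounter_type.strip().lower() in hospital_encounters)
    return treated, in_hospital


def compute_flags(sentence, mention: Mention, ctx: ContextLexicon,
                  section: str = "other",
                  note_date: dt.date | None = None,
                  encounter_type: str = "",
                  hospital_encounters: frozenset[str] =
                  DEFAULT_HOSPITAL_ENCOUNTERS,
                  year_threshold: int = 1,
                  header_phrases: Sequence[Phrase] = ()) -> ContextFlags:
    """Run every detector for one mention."""
    treated, in_hospital = detect_medication_treatment(
        sentence, mention, ctx, encounter_type, hospital_encounters,
        header_phrases)
    return ContextFlags(
        negated=detect_negation(sentence, mention, ctx, header_phrases),
        uncertain=detect_uncertainty(sentence, mention, ctx,
                                     header_phrases),
        definite=detect_definite(sentence, mention, ctx, header_phrases),
        historical=detect_historical(sentence, mention, ctx, note_date,
                                     year_threshold, header_phrases),
        non_patient=detect_non_patient(sentence, mention, ctx, section,
                                       header_phrases),
        generic_conditional=detect_generic_conditional(
            sentence, mention, ctx, header_phrases),
        medication_treated=treated,
        medication_in_hospital=in_hospital,
        checkbox_affirmed=detect_checkbox(sentence, mention, ctx, section),
        present_report=detect_present_report(sentence, mention, ctx,
                                             header_phrases),
        bare_term=detect_bare_term(sentence, mention),
    )
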