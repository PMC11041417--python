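"""Candidate symptom mention detection within one sentence.

Three match routes feed the classifier:

* direct trigger phrases (token-sequence match, maximal matches only,
  so ``pain`` inside ``abdominal pain`` is not a second mention);
* the composite DVT rule — a deep-vein-thrombosis symptom needs a body
  location term (which decides upper vs lower extremity) co-occurring
  with a feeling/appearance term, optionally plus a laterality term;
* the pain-proximity rule — abdominal/epigastric and back pain fire when
  a pain word and a body-location word are within ``max_pain_distance``
  token positions of each other.

A radiation-direction filter then removes mentions whose location is the
*target* of pain radiation ("pain radiating to the back" is not back
pain) while keeping DVT mentions whose extremity is the *source* ("pain
radiating from the left leg").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .lexicon import Phrase, SymptomLexicon
from .preprocess import Sentence
from .symptoms import DVT_SYMPTOMS, PAIN_SYMPTOMS

RADIATION_VERBS = frozenset({"radiating", "radiates", "radiated", "radiate"})
_RADIATION_TO = frozenset({"to", "into", "toward", "towards"})
_RADIATION_FROM = frozenset({"from"})


@dataclass
class Mention:
    """One matched symptom trigger (or composite) in one sentence."""

    symptom_id: str
    sentence_index: int
    spans: list[tuple[int, int]]          # token-index spans, half-open
    phrases: list[str]
    match_kind: str                       # phrase | dvt_composite | pain_proximity
    laterality: str | None = None
    location_index: int | None = None     # start of the body-location term

    @property
    def start(self) -> int:
        return min(s for s, _ in self.spans)

    @property
    def end(self) -> int:
        return max(e for _, e in self.spans)

    @property
    def token_count(self) -> int:
        return sum(e - s for s, e in self.spans)


def _forms(sentence: Sequence[str] | Sentence) -> list[str]:
    if isinstance(sentence, Sentence):
        return sentence.forms
    return list(sentence)


def phrase_occurrences(forms: Sequence[str],
                       phrase: Phrase) -> list[tuple[int, int]]:
    n = len(phrase)
    return [(i, i + n) for i in range(len(forms) - n + 1)
            if tuple(forms[i:i + n]) == phrase]


def find_phrase_mentions(sentence: Sequence[str] | Sentence,
                         lexicons: Mapping[str, SymptomLexicon],
                         sentence_index: int = 0) -> list[Mention]:
    """All maximal trigger-phrase occurrences per symptom.

    A match properly contained in another match of the same symptom is
    collapsed into the longer one.
    """
    forms = _forms(sentence)
    mentions: list[Mention] = []
    for sid in sorted(lexicons):
        lex = lexicons[sid]
        hits: list[tuple[int, int]] = []
        for phrase in lex.trigger_phrases:
            hits.extend(phrase_occurrences(forms, phrase))
        hits = sorted(set(hits))
        kept = [h for h in hits
                if not any(o != h and o[0] <= h[0] and h[1] <= o[1]
                           for o in hits)]
        for s, e in kept:
            mentions.append(Mention(
                symptom_id=sid, sentence_index=sentence_index,
                spans=[(s, e)], phrases=[" ".join(forms[s:e])],
                match_kind="phrase"))
    mentions.sort(key=lambda m: (m.start, m.symptom_id))
    return mentions


def _term_occurrences(forms: Sequence[str],
                      terms: set[Phrase]) -> list[tuple[int, int]]:
    occs: list[tuple[int, int]] = []
    for term in terms:
        occs.extend(phrase_occurrences(forms, term))
    return sorted(set(occs))


def find_dvt_mentions(sentence: Sequence[str] | Sentence,
                      lexicons: Mapping[str, SymptomLexicon],
                      require_laterality: bool = False,
                      sentence_index: int = 0) -> list[Mention]:
    """Composite DVT mentions: location + feeling (+ laterality) terms
    co-occurring in the sentence; the location set decides upper/lower."""
    forms = _forms(sentence)
    mentions: list[Mention] = []
    for sid in sorted(DVT_SYMPTOMS):
        lex = lexicons.get(sid)
        if lex is None:
            continue
        locs = _term_occurrences(forms, lex.dvt_location_terms)
        feels = _term_occurrences(forms, lex.dvt_feeling_terms)
        lats = _term_occurrences(forms, lex.dvt_laterality_terms)
        # a single token cannot serve as both location and feeling
        feels = [f for f in feels if not locs or f not in locs]
        if not locs or not feels:
            continue
        if require_laterality and not lats:
            continue
        loc, feel = locs[0], feels[0]
        spans = [loc, feel]
        phrases = [" ".join(forms[s:e]) for s, e in spans]
        laterality = None
        if lats:
            spans = spans + [lats[0]]
            phrases.append(" ".join(forms[lats[0][0]:lats[0][1]]))
            laterality = phrases[-1]
        mentions.append(Mention(
            symptom_id=sid, sentence_index=sentence_index,
            spans=spans, phrases=phrases, match_kind="dvt_composite",
            laterality=laterality, location_index=loc[0]))
    return mentions


def find_pain_proximity_mentions(sentence: Sequence[str] | Sentence,
                                 lexicons: Mapping[str, SymptomLexicon],
                                 sentence_index: int = 0) -> list[Mention]:
    """Pain term + body-location term within ``max_pain_distance`` token
    positions (absolute difference of start indices)."""
    forms = _forms(sentence)
    mentions: list[Mention] = []
    for sid in sorted(PAIN_SYMPTOMS):
        lex = lexicons.get(sid)
        if lex is None or not lex.pain_location_terms or not lex.pain_terms:
            continue
        locs = _term_occurrences(forms, lex.pain_location_terms)
        pains = _term_occurrences(forms, lex.pain_terms)
        best: tuple[int, int, tuple[int, int], tuple[int, int]] | None = None
        for loc in locs:
            for pain in pains:
                if loc == pain:
                    continue
                d = abs(loc[0] - pain[0])
                if d > lex.max_pain_distance:
                    continue
                key = (d, min(loc[0], pain[0]))
                if best is None or key < (best[0], best[1]):
                    best = (d, min(loc[0], pain[0]), loc, pain)
        if best is None:
            continue
        _, _, loc, pain = best
        mentions.append(Mention(
            symptom_id=sid, sentence_index=sentence_index,
            spans=[loc, pain],
            phrases=[" ".join(forms[s:e]) for s, e in (loc, pain)],
            match_kind="pain_proximity", location_index=loc[0]))
    return mentions


# ---------------------------------------------------------------------------
# Radiation-direction filtering

def _governed_locations(forms: Sequence[str],
                        window: int) -> dict[int, str]:
    """Token indices governed by a radiation construction, mapped to the
    direction ('to' or 'from').  The radiation verb must precede the
    location with at most ``window`` intervening tokens and be followed
    by a direction word within two positions."""
    governed: dict[int, str] = {}
    for i, form in enumerate(forms):
        if form not in RADIATION_VERBS:
            continue
        direction = None
        for j in (i + 1, i + 2):
            if j < len(forms):
                if forms[j] in _RADIATION_TO:
                    direction = "to"
                    break
                if forms[j] in _RADIATION_FROM:
                    direction = "from"
                    break
        if direction is None:
            continue
        for k in range(i + 1, min(len(forms), i + window + 2)):
            governed.setdefault(k, direction)
    return governed


def _location_indices(mention: Mention,
                      lexicons: Mapping[str, SymptomLexicon]) -> list[int]:
    if mention.location_index is not None:
        return [mention.location_index]
    lex = lexicons.get(mention.symptom_id)
    if lex is None:
        return []
    # phrase-kind mentions: any token of the trigger that is a location word
    out: list[int] = []
    for span, phrase in zip(mention.spans, mention.phrases):
        for off, w in enumerate(phrase.split()):
            if (w,) in lex.pain_location_terms:
                out.append(span[0] + off)
    return out


def filter_radiation(sentence: Sequence[str] | Sentence,
                     mentions: list[Mention],
                     lexicons: Mapping[str, SymptomLexicon],
                     window: int = 3) -> list[Mention]:
    """Drop pain mentions whose body location is the target of radiation
    ("radiating to ..."); keep DVT mentions only when radiation is *from*
    the extremity.  Mentions not governed by a radiation construction
    pass through unchanged."""
    forms = _forms(sentence)
    governed = _governed_locations(forms, window)
    if not governed:
        return list(mentions)
    kept: list[Mention] = []
    for m in mentions:
        if m.symptom_id in PAIN_SYMPTOMS:
            dirs = {governed[k] for k in _location_indices(m, lexicons)
                    if k in governed}
            if "to" in dirs:
                continue
        elif m.symptom_id in DVT_SYMPTOMS and m.location_index is not None:
            if governed.get(m.location_index) == "to":
                continue
        kept.append(m)
    return kept


# ---------------------------------------------------------------------------
# Combined entry point

def find_mentions(sentence: Sequence[str] | Sentence,
                  lexicons: Mapping[str, SymptomLexicon],
                  require_laterality: bool = False,
                  radiation_window: int = 3,
                  sentence_index: int = 0) -> list[Mention]:
    """All mentions in a sentence: phrase, DVT-composite and
    pain-proximity routes, de-duplicated and radiation-filtered."""
    mentions = find_phrase_mentions(sentence, lexicons, sentence_index)
    mentions += find_dvt_mentions(sentence, lexicons, require_laterality,
                                  sentence_index)
    proximity = find_pain_proximity_mentions(sentence, lexicons,
                                             sentence_index)
    # a proximity hit overlapping a direct phrase hit of the same symptom
    # is the same locus; keep the phrase mention
    for p in proximity:
        clash = any(
            m.symptom_id == p.symptom_id and m.match_kind == "phrase"
            and any(ps < me and ms < pe
                    for ps, pe in p.spans for ms, me in m.spans)
            for m in mentions)
        if not clash:
            mentions.append(p)
    mentions = filter_radiation(sentence, mentions, lexicons,
                                radiation_window)
    mentions.sort(key=lambda m: (m.start, m.symptom_id, m.match_kind))
    return mentions
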