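import itertools
import random

import pytest

from oracles import oracle_mentions, oracle_phrase_spans
from pdacsym.lexicon import SymptomLexicon
from pdacsym.matcher import (find_dvt_mentions, find_mentions,
                             find_pain_proximity_mentions,
                             find_phrase_mentions, filter_radiation)


@pytest.fixture(scope="module")
def mini():
    """Reduced lexicon for exhaustive oracle comparison."""
    return {
        "jaundice": SymptomLexicon(
            "jaundice",
            trigger_phrases=[("jaundice",), ("yellow", "skin")]),
        "abdominal_epigastric_pain": SymptomLexicon(
            "abdominal_epigastric_pain",
            trigger_phrases=[("abdominal", "pain")],
            pain_location_terms={("abdominal",)},
            pain_terms={("pain",)}),
        "back_pain": SymptomLexicon(
            "back_pain",
            trigger_phrases=[("back", "pain")],
            pain_location_terms={("back",)},
            pain_terms={("pain",)}),
        "dvt_lower": SymptomLexicon(
            "dvt_lower",
            dvt_location_terms={("leg",)},
            dvt_feeling_terms={("pain",), ("swollen",)},
            dvt_laterality_terms={("left",)}),
        "dvt_upper": SymptomLexicon(
            "dvt_upper",
            dvt_location_terms={("arm",)},
            dvt_feeling_terms={("pain",), ("swollen",)},
            dvt_laterality_terms={("left",)}),
    }


class TestPhrase:
    def test_multiple_symptoms_one_sentence(self, symptom_lexicons):
        forms = ["positive", "for", "fatigue", "and", "weight", "loss"]
        got = {m.symptom_id for m in
               find_phrase_mentions(forms, symptom_lexicons)}
        assert got == {"fatigue", "weight_loss"}

    def test_no_trigger_no_mentions(self, symptom_lexicons):
        assert find_phrase_mentions(["doing", "well"],
                                    symptom_lexicons) == []

    def test_contained_match_collapses_to_longest(self, mini):
        mini2 = dict(mini)
        mini2["jaundice"] = SymptomLexicon(
            "jaundice", trigger_phrases=[("skin",), ("yellow", "skin")])
        got = find_phrase_mentions(["yellow", "skin"], mini2)
        assert [(m.spans, m.phrases) for m in got] == [
            ([(0, 2)], ["yellow skin"])]

    def test_lexicon_order_irrelevant(self, mini):
        forms = ["yellow", "skin", "and", "jaundice"]
        base = find_phrase_mentions(forms, mini)
        reordered = dict(mini)
        reordered["jaundice"] = SymptomLexicon(
            "jaundice",
            trigger_phrases=[("yellow", "skin"), ("jaundice",)])
        again = find_phrase_mentions(forms, reordered)
        assert [(m.symptom_id, m.spans) for m in base] == \
               [(m.symptom_id, m.spans) for m in again]

    def test_adding_phrase_never_removes_mentions(self, mini):
        forms = ["jaundice", "with", "yellow", "skin"]
        before = {(m.symptom_id, tuple(m.spans))
                  for m in find_phrase_mentions(forms, mini)}
        grown = dict(mini)
        grown["fatigue"] = SymptomLexicon("fatigue",
                                          trigger_phrases=[("with",)])
        after = {(m.symptom_id, tuple(m.spans))
                 for m in find_phrase_mentions(forms, grown)}
        assert before <= after


class TestDvt:
    def test_location_feeling_laterality(self, symptom_lexicons):
        got = find_dvt_mentions(["left", "leg", "swollen"],
                                symptom_lexicons)
        assert [(m.symptom_id, m.laterality) for m in got] == [
            ("dvt_lower", "left")]

    def test_laterality_optional_by_default(self, symptom_lexicons):
        got = find_dvt_mentions(["leg", "swollen"], symptom_lexicons)
        assert [(m.symptom_id, m.laterality) for m in got] == [
            ("dvt_lower", None)]
        assert find_dvt_mentions(["leg", "swollen"], symptom_lexicons,
                                 require_laterality=True) == []

    def test_missing_feeling_term_no_mention(self, symptom_lexicons):
        assert find_dvt_mentions(["arm", "is", "fine"],
                                 symptom_lexicons) == []

    def test_location_set_decides_extremity(self, symptom_lexicons):
        got = find_dvt_mentions(["right", "arm", "swelling"],
                                symptom_lexicons)
        assert [m.symptom_id for m in got] == ["dvt_upper"]


class TestPainProximity:
    def test_within_distance(self, symptom_lexicons):
        got = find_pain_proximity_mentions(
            ["severe", "abdominal", "cramping", "pain"], symptom_lexicons)
        assert [m.symptom_id for m in got] == ["abdominal_epigastric_pain"]

    def test_beyond_distance_no_mention(self, symptom_lexicons):
        forms = ["abdominal", "a", "b", "c", "d", "e", "f", "pain"]
        assert find_pain_proximity_mentions(forms, symptom_lexicons) == []

    def test_location_alone_insufficient(self, symptom_lexicons):
        assert find_pain_proximity_mentions(["back"],
                                            symptom_lexicons) == []


class TestRadiation:
    def test_radiating_to_back_dropped(self, symptom_lexicons):
        forms = ["pain", "radiating", "to", "the", "back"]
        mentions = find_mentions(forms, symptom_lexicons)
        assert all(m.symptom_id != "back_pain" for m in mentions)

    def test_radiating_from_leg_kept(self, symptom_lexicons):
        forms = ["pain", "radiating", "from", "the", "left", "leg"]
        got = {m.symptom_id for m in
               find_mentions(forms, symptom_lexicons)}
        assert "dvt_lower" in got

    def test_radiating_to_leg_drops_dvt(self, symptom_lexicons):
        forms = ["pain", "radiating", "to", "the", "left", "leg"]
        got = {m.symptom_id for m in
               find_mentions(forms, symptom_lexicons)}
        assert "dvt_lower" not in got

    def test_without_radiation_verb_unchanged(self, symptom_lexicons):
        forms = ["pain", "in", "the", "back"]
        mentions = find_phrase_mentions(forms, symptom_lexicons) + \
            find_pain_proximity_mentions(forms, symptom_lexicons)
        kept = filter_radiation(forms, mentions, symptom_lexicons)
        assert kept == mentions


class TestOracleEquivalence:
    VOCAB = ("jaundice", "yellow", "skin", "pain", "abdominal", "back",
             "leg", "left", "swollen", "radiating", "to", "from")

    def check(self, forms, mini):
        got = {(m.symptom_id, m.match_kind)
               for m in find_mentions(forms, mini)}
        assert got == oracle_mentions(forms, mini), forms
        for sid, lex in mini.items():
            spans = {tuple(m.spans[0]) for m in
                     find_phrase_mentions(forms, {sid: lex})}
            assert spans == oracle_phrase_spans(forms, lex), (forms, sid)

    def test_exhaustive_short_sentences(self, mini):
        for n in range(1, 4):
            for forms in itertools.product(self.VOCAB, repeat=n):
                self.check(list(forms), mini)

    def test_random_longer_sentences(self, mini):
        rng = random.Random(20240917)
        for _ in range(1500):
            n = rng.randint(4, 12)
            forms = [rng.choice(self.VOCAB) for _ in range(n)]
            self.check(forms, mini)
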