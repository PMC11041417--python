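import datetime as dt

import pytest

from pdacsym.context import (compute_flags, detect_checkbox,
                             detect_definite, detect_generic_conditional,
                             detect_historical,
                             detect_medication_treatment, detect_negation,
                             detect_non_patient, detect_uncertainty)
from pdacsym.matcher import find_mentions, find_phrase_mentions

NOTE_DATE = dt.date(2015, 6, 1)


def mention_for(forms, symptom_id, symptom_lexicons):
    mentions = [m for m in find_mentions(forms, symptom_lexicons)
                if m.symptom_id == symptom_id]
    assert mentions, (forms, symptom_id)
    return mentions[0]


class TestNegation:
    def test_cue_covers_listed_triggers(self, symptom_lexicons, ctx):
        forms = ["patient", "denied", "vomiting", "nausea"]
        for m in find_phrase_mentions(forms, symptom_lexicons):
            assert detect_negation(forms, m, ctx)

    def test_simple_no(self, symptom_lexicons, ctx):
        forms = ["no", "pruritus"]
        m = mention_for(forms, "pruritus", symptom_lexicons)
        assert detect_negation(forms, m, ctx)

    def test_but_breaks_scope(self, symptom_lexicons, ctx):
        forms = ["denies", "nausea", "but", "reports", "back", "pain"]
        nausea = mention_for(forms, "nausea_vomiting", symptom_lexicons)
        back = mention_for(forms, "back_pain", symptom_lexicons)
        assert detect_negation(forms, nausea, ctx)
        assert not detect_negation(forms, back, ctx)

    def test_cue_after_trigger_does_not_negate(self, symptom_lexicons,
                                               ctx):
        forms = ["nausea", "resolved", "no", "issues"]
        m = mention_for(forms, "nausea_vomiting", symptom_lexicons)
        assert not detect_negation(forms, m, ctx)

    def test_list_distribution_with_breaker(self, symptom_lexicons, ctx):
        listed = ["denies", "nausea", "itching", "fatigue"]
        for m in find_phrase_mentions(listed, symptom_lexicons):
            assert detect_negation(listed, m, ctx)
        broken = ["denies", "nausea", "itching", "but", "fatigue"]
        for m in find_phrase_mentions(broken, symptom_lexicons):
            expected = m.phrases[0] != "fatigue"
            assert detect_negation(broken, m, ctx) is expected


class TestUncertainty:
    def test_likely_scopes_forward_only(self, symptom_lexicons, ctx):
        forms = ["patient", "with", "anxiety", "and", "likely",
                 "depression"]
        anxiety = mention_for(forms, "anxiety", symptom_lexicons)
        depression = mention_for(forms, "depression", symptom_lexicons)
        assert not detect_uncertainty(forms, anxiety, ctx)
        assert detect_uncertainty(forms, depression, ctx)

    def test_may_be(self, symptom_lexicons, ctx):
        forms = ["there", "may", "be", "pruritus", "or", "pain"]
        m = mention_for(forms, "pruritus", symptom_lexicons)
        assert detect_uncertainty(forms, m, ctx)

    def test_no_cue_false(self, symptom_lexicons, ctx):
        forms = ["reports", "pruritus"]
        m = mention_for(forms, "pruritus", symptom_lexicons)
        assert not detect_uncertainty(forms, m, ctx)


class TestHistorical:
    def test_relative_phrase(self, symptom_lexicons, ctx):
        forms = ["patient", "had", "abdominal", "pain", "two", "years",
                 "ago"]
        m = mention_for(forms, "abdominal_epigastric_pain",
                        symptom_lexicons)
        assert detect_historical(forms, m, ctx, NOTE_DATE)

    def test_old_explicit_year(self, symptom_lexicons, ctx):
        forms = ["patient", "had", "jaundice", "in", "2007"]
        m = mention_for(forms, "jaundice", symptom_lexicons)
        assert detect_historical(forms, m, ctx, NOTE_DATE)

    def test_recent_complaint_not_historical(self, symptom_lexicons, ctx):
        forms = ["abdominal", "pain", "since", "yesterday"]
        m = mention_for(forms, "abdominal_epigastric_pain",
                        symptom_lexicons)
        assert not detect_historical(forms, m, ctx, NOTE_DATE)

    def test_since_year_marks_onset_not_history(self, symptom_lexicons,
                                                ctx):
        forms = ["weight", "loss", "since", "march", "2009"]
        m = mention_for(forms, "weight_loss", symptom_lexicons)
        assert not detect_historical(forms, m, ctx, NOTE_DATE)

    def test_unknown_note_date_ignores_year(self, symptom_lexicons, ctx):
        forms = ["jaundice", "in", "2007"]
        m = mention_for(forms, "jaundice", symptom_lexicons)
        assert not detect_historical(forms, m, ctx, None)


class TestExperiencer:
    def test_family_member_cue(self, symptom_lexicons, ctx):
        forms = ["my", "husband", "is", "in", "a", "deep", "depression"]
        m = mention_for(forms, "depression", symptom_lexicons)
        assert detect_non_patient(forms, m, ctx)

    def test_daughter_in_law(self, symptom_lexicons, ctx):
        forms = ["daughter", "in", "law", "has", "been", "stressed",
                 "poor", "appetite"]
        m = mention_for(forms, "anorexia_early_satiety", symptom_lexicons)
        assert detect_non_patient(forms, m, ctx)

    def test_patient_report_is_patient(self, symptom_lexicons, ctx):
        forms = ["patient", "reports", "anorexia"]
        m = mention_for(forms, "anorexia_early_satiety", symptom_lexicons)
        assert not detect_non_patient(forms, m, ctx)

    def test_family_history_section_forces_non_patient(
            self, symptom_lexicons, ctx):
        forms = ["anxiety"]
        m = mention_for(forms, "anxiety", symptom_lexicons)
        assert detect_non_patient(forms, m, ctx,
                                  section="family_history")


class TestGenericConditional:
    def test_return_if(self, symptom_lexicons, ctx):
        forms = ["return", "if", "you", "experience", "epigastric",
                 "bloating"]
        m = mention_for(forms, "epigastric_bloating", symptom_lexicons)
        assert detect_generic_conditional(forms, m, ctx)

    def test_side_effect_list_covers_all(self, symptom_lexicons, ctx):
        forms = ["glipizide", "side", "effects", "including", "loss",
                 "of", "appetite", "nausea", "vomiting", "weight", "gain"]
        mentions = find_phrase_mentions(forms, symptom_lexicons)
        assert {m.symptom_id for m in mentions} == {
            "anorexia_early_satiety", "nausea_vomiting"}
        for m in mentions:
            assert detect_generic_conditional(forms, m, ctx)

    def test_plain_report_false(self, symptom_lexicons, ctx):
        forms = ["reports", "nausea"]
        m = mention_for(forms, "nausea_vomiting", symptom_lexicons)
        assert not detect_generic_conditional(forms, m, ctx)


class TestCheckboxAndBare:
    def test_marker_adjacency(self, symptom_lexicons, ctx):
        forms = ["nausea", "yes", "vomiting", "no"]
        mentions = find_phrase_mentions(forms, symptom_lexicons)
        flags = {m.phrases[0]: detect_checkbox(forms, m, ctx)
                 for m in mentions}
        assert flags == {"nausea": True, "vomiting": False}

    def test_x_marker(self, symptom_lexicons, ctx):
        forms = ["fatigue", "x"]
        m = mention_for(forms, "fatigue", symptom_lexicons)
        assert detect_checkbox(forms, m, ctx)

    def test_bare_term_flagged(self, symptom_lexicons, ctx):
        forms = ["fatigue"]
        m = mention_for(forms, "fatigue", symptom_lexicons)
        flags = compute_flags(forms, m, ctx)
        assert flags.bare_term and not flags.checkbox_affirmed

    def test_preceding_marker_only_in_symptom_list(self, symptom_lexicons,
                                                   ctx):
        forms = ["x", "fatigue"]
        m = mention_for(forms, "fatigue", symptom_lexicons)
        assert not detect_checkbox(forms, m, ctx, section="other")
        assert detect_checkbox(forms, m, ctx, section="symptom_list")


class TestDefiniteAndMedication:
    def test_positive_for_covers_conjunction(self, symptom_lexicons, ctx):
        forms = ["positive", "for", "fatigue", "and", "weight", "loss"]
        for m in find_phrase_mentions(forms, symptom_lexicons):
            assert detect_definite(forms, m, ctx)

    def test_presents_with_covers_list(self, symptom_lexicons, ctx):
        forms = ["patient", "presents", "with", "anxiety", "depression",
                 "insomnia"]
        mentions = find_phrase_mentions(forms, symptom_lexicons)
        assert len(mentions) == 3
        for m in mentions:
            assert detect_definite(forms, m, ctx)

    def test_medication_outpatient_vs_hospital(self, symptom_lexicons,
                                               ctx):
        forms = ["ondansetron", "given", "for", "nausea"]
        m = mention_for(forms, "nausea_vomiting", symptom_lexicons)
        assert detect_medication_treatment(
            forms, m, ctx, "outpatient") == (True, False)
        assert detect_medication_treatment(
            forms, m, ctx, "hospital") == (True, True)
        assert detect_medication_treatment(
            forms, m, ctx, "emergency") == (True, False)

    def test_no_medication_cue(self, symptom_lexicons, ctx):
        forms = ["patient", "reports", "nausea"]
        m = mention_for(forms, "nausea_vomiting", symptom_lexicons)
        assert detect_medication_treatment(
            forms, m, ctx, "hospital") == (False, False)


class TestPurityAndCueRemoval:
    SENTENCES = [
        ["patient", "denies", "nausea"],
        ["possible", "jaundice"],
        ["return", "if", "you", "experience", "itching"],
        ["my", "husband", "has", "fatigue"],
        ["patient", "had", "back", "pain", "two", "years", "ago"],
    ]

    def test_detectors_are_pure(self, symptom_lexicons, ctx):
        for forms in self.SENTENCES:
            for m in find_mentions(forms, symptom_lexicons):
                a = compute_flags(forms, m, ctx, note_date=NOTE_DATE)
                b = compute_flags(forms, m, ctx, note_date=NOTE_DATE)
                assert a == b

    def test_removing_cues_clears_all_flags_except_bare(
            self, symptom_lexicons, ctx):
        empty = ctx.without_cues()
        for forms in self.SENTENCES:
            for m in find_mentions(forms, symptom_lexicons):
                flags = compute_flags(forms, m, empty,
                                      note_date=NOTE_DATE)
                assert not any([
                    flags.negated, flags.uncertain, flags.definite,
                    flags.non_patient, flags.generic_conditional,
                    flags.medication_treated, flags.checkbox_affirmed,
                    flags.present_report])
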