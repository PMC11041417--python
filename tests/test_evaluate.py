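import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score

from oracles import oracle_kappa
from pdacsym.evaluate import (ConfusionCounts, cohens_kappa, confusion,
                              discrepancy_report, format_metrics,
                              load_reference_validation, metrics,
                              metrics_table, percent_agreement,
                              pooled_kappa)
from pdacsym.classifier import run_pipeline, results_to_frame
from pdacsym.preprocess import RawNote
from pdacsym.symptoms import SYMPTOMS


def frame(rows):
    """rows: {note_id: set of positive symptoms}"""
    data = {nid: [sid in pos for sid in SYMPTOMS]
            for nid, pos in rows.items()}
    f = pd.DataFrame.from_dict(data, orient="index",
                               columns=list(SYMPTOMS))
    f.index.name = "note_id"
    return f


class TestConfusion:
    def test_perfect_prediction(self):
        gold = frame({f"n{i}": ({"jaundice"} if i < 10 else set())
                      for i in range(100)})
        c = confusion(gold, gold)["jaundice"]
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 90, 0, 0)

    def test_all_negative_prediction(self):
        gold = frame({f"n{i}": ({"jaundice"} if i < 10 else set())
                      for i in range(100)})
        pred = frame({f"n{i}": set() for i in range(100)})
        c = confusion(gold, pred)["jaundice"]
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 90, 0, 10)

    def test_hand_enumerated_six_note_fixture(self):
        gold = frame({"a": {"fatigue"}, "b": {"fatigue"}, "c": set(),
                      "d": {"fatigue", "jaundice"}, "e": set(),
                      "f": {"jaundice"}})
        pred = frame({"a": {"fatigue"}, "b": set(), "c": {"fatigue"},
                      "d": {"fatigue"}, "e": set(), "f": {"jaundice"}})
        c = confusion(gold, pred)
        assert (c["fatigue"].tp, c["fatigue"].fp, c["fatigue"].tn,
                c["fatigue"].fn) == (2, 1, 2, 1)
        assert (c["jaundice"].tp, c["jaundice"].fp, c["jaundice"].tn,
                c["jaundice"].fn) == (1, 0, 4, 1)
        assert all(c[sid].total == 6 for sid in SYMPTOMS)

    def test_mismatched_note_sets_error_lists_ids(self):
        gold = frame({"a": set(), "b": set()})
        pred = frame({"a": set(), "c": set()})
        with pytest.raises(ValueError, match="'b'.*'c'"):
            confusion(gold, pred)


class TestMetrics:
    def test_published_jaundice_row(self):
        got = format_metrics(metrics(ConfusionCounts(
            "jaundice", tp=90, tn=905, fp=1, fn=4)))
        assert got["sensitivity_pct"] == 95.7
        assert got["ppv_pct"] == 98.9
        assert got["f1"] == 0.97

    def test_published_abdominal_pain_row(self):
        got = format_metrics(metrics(ConfusionCounts(
            "abdominal_epigastric_pain", tp=156, tn=824, fp=4, fn=16)))
        assert got["specificity_pct"] == 99.5
        assert got["npv_pct"] == 98.1

    def test_zero_denominator_flagged_not_fabricated(self):
        ms = metrics(ConfusionCounts("pale_stool", tp=0, tn=10, fp=0,
                                     fn=0))
        assert ms.sensitivity is None
        assert "sensitivity" in ms.undefined and "f1" in ms.undefined
        assert ms.specificity == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts("x", tp=-1, tn=0, fp=0, fn=0))

    def test_gold_vs_gold_metrics_all_one(self):
        gold = frame({f"n{i}": ({"fatigue"} if i % 3 == 0 else set())
                      for i in range(30)})
        for c in confusion(gold, gold).values():
            ms = metrics(c)
            for name in ("sensitivity", "specificity", "ppv", "npv",
                         "f1"):
                v = getattr(ms, name)
                assert v is None or v == 1.0

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500))
    @settings(max_examples=300, deadline=None)
    def test_f1_between_min_and_max_of_ppv_and_sensitivity(
            self, tp, fp, tn, fn):
        ms = metrics(ConfusionCounts("x", tp=tp, fp=fp, tn=tn, fn=fn))
        if ms.f1 is None:
            return
        lo, hi = sorted((ms.ppv, ms.sensitivity))
        assert lo - 1e-12 <= ms.f1 <= hi + 1e-12
        if ms.ppv == ms.sensitivity:
            assert ms.f1 == pytest.approx(ms.ppv)


class TestAgreementAndKappa:
    def test_agreement_examples(self):
        assert percent_agreement([1, 0, 1], [1, 0, 1]) == 1.0
        a = [1] * 50 + [0] * 50
        b = list(a)
        b[0] = 0
        assert percent_agreement(a, b) == 0.99

    def test_kappa_worked_example(self):
        # 1000 notes: rater A marks 90 yes; raters agree on 85 yes and
        # 905 no with 5+5 crossed -> p_o=0.99, p_e=0.8362, kappa=0.9389
        a = [1] * 90 + [0] * 910
        b = [1] * 85 + [0] * 5 + [1] * 5 + [0] * 905
        k = cohens_kappa(a, b)
        assert k == pytest.approx(0.93895, abs=1e-4)
        assert k == pytest.approx(oracle_kappa(a, b))

    def test_perfect_agreement_both_classes(self):
        assert cohens_kappa([0, 1, 1, 0], [0, 1, 1, 0]) == 1.0

    def test_one_rater_constant_gives_zero(self):
        a = [1, 1, 1, 1]
        b = [1, 1, 0, 0]
        assert cohens_kappa(a, b) == pytest.approx(0.0)

    def test_degenerate_identical_constant_flagged_undefined(self):
        assert cohens_kappa([1, 1, 1], [1, 1, 1]) is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            percent_agreement([1], [1, 0])
        with pytest.raises(ValueError, match="length mismatch"):
            cohens_kappa([1], [1, 0])

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=2, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_bounds_and_sklearn_agreement(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        k = cohens_kappa(a, b)
        if k is None:
            return
        assert k == pytest.approx(cohens_kappa(b, a))
        assert -1.0 - 1e-9 <= k <= 1.0 + 1e-9
        assert k == pytest.approx(cohen_kappa_score(a, b), abs=1e-9)

    def test_pooled_kappa_concatenates(self):
        gold = frame({"a": {"fatigue"}, "b": set(), "c": {"jaundice"}})
        assert pooled_kappa(gold, gold) == 1.0


class TestDiscrepancyReport:
    def run_notes(self, notes, lexicons):
        from pdacsym.classifier import PipelineConfig
        from pdacsym.preprocess import NoteExclusions
        results, _ = run_pipeline(
            notes, lexicons,
            PipelineConfig(exclusions=NoteExclusions.none()))
        return results, results_to_frame(results)

    def test_categories_from_reason_codes(self, lexicons):
        notes = [
            RawNote("fp_instr",
                    text="instructions: patient reports nausea"),
            RawNote("fn_neg", text="patient denies jaundice"),
            RawNote("fn_missing", text="nothing relevant here"),
            RawNote("fn_hist",
                    note_date=None,
                    text="patient had itching two years ago"),
        ]
        results, pred = self.run_notes(notes, lexicons)
        gold = frame({"fp_instr": set(), "fn_neg": {"jaundice"},
                      "fn_missing": {"fatigue"},
                      "fn_hist": {"pruritus"}})
        report = discrepancy_report(gold, pred, results, lexicons[1])
        by_note = report.set_index("note_id")
        assert by_note.loc["fp_instr", "kind"] == "FP"
        assert by_note.loc["fp_instr", "category"] == "instructions"
        assert by_note.loc["fn_neg", "category"] == "false_negation"
        assert by_note.loc["fn_missing", "category"] == "missing_term"
        assert by_note.loc["fn_hist", "category"] == \
            "history_misclassification"

    def test_no_discrepancies_empty_report(self, lexicons):
        notes = [RawNote("a", text="patient reports jaundice")]
        results, pred = self.run_notes(notes, lexicons)
        report = discrepancy_report(pred, pred, results, lexicons[1])
        assert report.empty


class TestReferenceTable:
    def test_reference_counts_shape_and_totals(self):
        ref = load_reference_validation().set_index("symptom_id")
        assert len(ref) == 17
        assert set(ref.index) == set(SYMPTOMS)
        totals = ref.tp + ref.tn + ref.fp + ref.fn
        # nausea/vomiting was scored on fewer notes: hospital encounters
        # are excluded for that symptom (emergency excepted)
        assert totals["nausea_vomiting"] == 927
        assert (totals.drop("nausea_vomiting") == 1000).all()

    def test_metrics_table_layout(self):
        ref = load_reference_validation()
        counts = {r.symptom_id: ConfusionCounts(
            r.symptom_id, tp=r.tp, tn=r.tn, fp=r.fp, fn=r.fn)
            for r in ref.itertuples()}
        table = metrics_table(counts)
        assert list(table.symptom_id) == list(SYMPTOMS)
        assert {"sensitivity_pct", "ppv_pct", "f1"} <= set(table.columns)
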