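"""Scoring of note-level predictions against gold labels.

Implements the standard extraction metrics — sensitivity (recall),
specificity, PPV (precision), NPV and F1 = 2·PPV·sens/(PPV+sens) — from
per-symptom TP/FP/TN/FN counts, percent agreement and Cohen's kappa for
dual-annotated subsets, and a categorized discrepancy (FP/FN) report
driven by the classifier's reason codes.

Zero-denominator metrics are surfaced as ``None`` and flagged undefined
rather than silently coerced to 0 or 1, which matters for rare symptoms.
Percentages are conventionally reported to one decimal and F1 to two.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import NoteResult, results_to_frame
from .lexicon import ContextLexicon
from .symptoms import SYMPTOMS


@dataclass
class ConfusionCounts:
    symptom_id: str
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    undefined: set[str] = field(default_factory=set)


def _ratio(num: int, den: int, name: str,
           undefined: set[str]) -> float | None:
    if den == 0:
        undefined.add(name)
        return None
    return num / den


def metrics(c: ConfusionCounts) -> MetricSet:
    """Derive the five performance metrics from confusion counts."""
    if min(c.tp, c.fp, c.tn, c.fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    undefined: set[str] = set()
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity", undefined)
    spec = _ratio(c.tn, c.tn + c.fp, "specificity", undefined)
    ppv = _ratio(c.tp, c.tp + c.fp, "ppv", undefined)
    npv = _ratio(c.tn, c.tn + c.fn, "npv", undefined)
    if sens is None or ppv is None or (sens + ppv) == 0:
        undefined.add("f1")
        f1 = None
    else:
        f1 = 2 * ppv * sens / (ppv + sens)
    return MetricSet(sens, spec, ppv, npv, f1, undefined)


def round_half_up(value: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_metrics(ms: MetricSet) -> dict[str, float | None]:
    """Percentages to 1 decimal, F1 to 2 decimals (reporting precision)."""
    out: dict[str, float | None] = {}
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        v = getattr(ms, name)
        out[f"{name}_pct"] = (None if v is None
                              else round_half_up(100 * v, 1))
    out["f1"] = None if ms.f1 is None else round_half_up(ms.f1, 2)
    return out


# ---------------------------------------------------------------------------
# Confusion counts from note-level labels

def _as_frame(labels) -> pd.DataFrame:
    if isinstance(labels, pd.DataFrame):
        frame = labels.copy()
    else:
        frame = results_to_frame(labels)
    missing = [sid for sid in SYMPTOMS if sid not in frame.columns]
    if missing:
        raise ValueError(f"label table lacks symptom columns: {missing}")
    return frame[list(SYMPTOMS)].astype(bool)


def confusion(gold, pred) -> dict[str, ConfusionCounts]:
    """Per-symptom confusion counts over an identical set of notes.

    ``gold``/``pred`` may be note-by-symptom boolean DataFrames (index
    note_id) or iterables of :class:`NoteResult`.
    """
    g = _as_frame(gold)
    p = _as_frame(pred)
    only_gold = sorted(set(g.index) - set(p.index))
    only_pred = sorted(set(p.index) - set(g.index))
    if only_gold or only_pred:
        raise ValueError(
            "gold and prediction note sets differ; only in gold: "
            f"{only_gold[:10]}, only in predictions: {only_pred[:10]}")
    p = p.loc[g.index]
    counts: dict[str, ConfusionCounts] = {}
    for sid in SYMPTOMS:
        gv = g[sid].to_numpy()
        pv = p[sid].to_numpy()
        counts[sid] = ConfusionCounts(
            symptom_id=sid,
            tp=int(np.sum(gv & pv)), fp=int(np.sum(~gv & pv)),
            tn=int(np.sum(~gv & ~pv)), fn=int(np.sum(gv & ~pv)))
    return counts


def metrics_table(counts: Mapping[str, ConfusionCounts]) -> pd.DataFrame:
    rows = []
    for sid in SYMPTOMS:
        if sid not in counts:
            continue
        c = counts[sid]
        row = {"symptom_id": sid, "tp": c.tp, "tn": c.tn,
               "fp": c.fp, "fn": c.fn}
        row.update(format_metrics(metrics(c)))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Interrater reliability

def percent_agreement(a: Sequence, b: Sequence) -> float:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(a == b))


def cohens_kappa(a: Sequence, b: Sequence) -> float | None:
    """Chance-corrected agreement (p_o − p_e)/(1 − p_e) with
    marginal-product expected agreement; ``None`` when p_e = 1."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    n = a.size
    if n == 0:
        raise ValueError("empty label vectors")
    labels = np.union1d(a, b)
    p_o = float(np.mean(a == b))
    p_e = sum(float(np.mean(a == lab)) * float(np.mean(b == lab))
              for lab in labels)
    if p_e >= 1.0:
        return None
    return (p_o - p_e) / (1 - p_e)


def kappa_by_symptom(gold, pred) -> dict[str, float | None]:
    g = _as_frame(gold)
    p = _as_frame(pred).loc[_as_frame(gold).index]
    return {sid: cohens_kappa(g[sid].to_numpy(), p[sid].to_numpy())
            for sid in SYMPTOMS}


def pooled_kappa(gold, pred) -> float | None:
    """Kappa over all (note, symptom) pairs concatenated."""
    g = _as_frame(gold)
    p = _as_frame(pred).loc[g.index]
    return cohens_kappa(g.to_numpy().ravel(), p.to_numpy().ravel())


# ---------------------------------------------------------------------------
# Discrepancy analysis

FP_CATEGORIES = ("problem_list", "instructions", "negation_failure",
                 "past_history", "other")
FN_CATEGORIES = ("false_negation", "missing_term",
                 "history_misclassification", "medication_instruction",
                 "other")


def _fp_category(decisions, ctx: ContextLexicon | None) -> tuple[str, str]:
    yes = [d for d in decisions if d.decision == "yes"]
    evidence = yes[0].evidence_text if yes else ""
    for d in yes:
        if d.section_label == "instructions":
            return "instructions", d.evidence_text
    for d in yes:
        if d.section_label == "past_medical_history":
            return "past_history", d.evidence_text
    for d in yes:
        if d.section_label in ("diagnosis", "medications"):
            return "problem_list", d.evidence_text
    if ctx is not None:
        cues = {" ".join(c) for c in ctx.negation_terms}
        for d in yes:
            words = d.evidence_text.split()
            grams = {" ".join(words[i:j]) for i in range(len(words))
                     for j in range(i + 1, min(i + 4, len(words)) + 1)}
            if grams & cues:
                return "negation_failure", d.evidence_text
    return "other", evidence


def _fn_category(decisions) -> tuple[str, str]:
    if not decisions:
        return "missing_term", ""
    reasons = {d.reason_code for d in decisions}
    evidence = decisions[0].evidence_text
    if "NO_NEGATED" in reasons:
        return "false_negation", evidence
    if "NO_HISTORICAL" in reasons:
        return "history_misclassification", evidence
    if reasons & {"NO_MEDICATION_HOSPITAL", "NO_GENERIC_CONDITIONAL"}:
        return "medication_instruction", evidence
    return "other", evidence


def discrepancy_report(gold, pred, results: Iterable[NoteResult],
                       ctx: ContextLexicon | None = None) -> pd.DataFrame:
    """Categorize every FP and FN using the classifier's reason codes
    and the evidence sentence's section."""
    g = _as_frame(gold)
    p = _as_frame(pred).loc[g.index]
    by_id = {r.note_id: r for r in results}
    rows = []
    for note_id in g.index:
        result = by_id.get(note_id)
        for sid in SYMPTOMS:
            gv, pv = bool(g.at[note_id, sid]), bool(p.at[note_id, sid])
            if gv == pv:
                continue
            decisions = ([d for d in result.decisions
                          if d.symptom_id == sid] if result else [])
            if pv and not gv:
                category, evidence = _fp_category(decisions, ctx)
                kind = "FP"
            else:
                category, evidence = _fn_category(decisions)
                kind = "FN"
            rows.append({"note_id": note_id, "symptom_id": sid,
                         "kind": kind, "category": category,
                         "evidence": evidence})
    return pd.DataFrame(rows, columns=["note_id", "symptom_id", "kind",
                                       "category", "evidence"])


# ---------------------------------------------------------------------------
# Published reference counts

def load_reference_validation() -> pd.DataFrame:
    """Published validation confusion counts (1000 notes) with the metric
    values as printed in the source report (inputs, not package output)."""
    text = (resources.files("pdacsym")
            .joinpath("data/reference_validation_counts.tsv")
            .read_text(encoding="utf-8"))
    body = "\n".join(line for line in text.splitlines()
                     if not line.startswith("#"))
    return pd.read_csv(io.StringIO(body), sep="\t")
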