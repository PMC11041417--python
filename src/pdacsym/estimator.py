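"""scikit-learn-compatible front end for the symptom extractor.

The extractor is a deterministic rule system, so :meth:`fit` performs no
learning: it loads and validates the lexicons and freezes the rule
configuration into fitted attributes.  :meth:`predict` maps notes to the
note-by-symptom boolean matrix, which composes with scikit-learn metric
and model-selection utilities (multi-label layout, one column per
symptom in canonical order).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .classifier import (NoteResult, PipelineConfig, classify_note,
                         run_pipeline)
from .lexicon import default_lexicons, load_lexicons, validate_lexicons
from .preprocess import NoteExclusions, RawNote
from .sections import default_header_patterns, load_header_patterns
from .symptoms import SYMPTOMS


def _as_notes(X) -> list[RawNote]:
    if isinstance(X, pd.DataFrame):
        notes = []
        for _, row in X.iterrows():
            notes.append(RawNote(
                note_id=str(row["note_id"]),
                patient_id=str(row.get("patient_id", "")),
                group=str(row.get("group", "unknown")),
                note_date=row.get("note_date", None) or None,
                encounter_type=str(row.get("encounter_type", "")),
                note_type=str(row.get("note_type", "")),
                department=str(row.get("department", "")),
                text=str(row.get("text", ""))))
        return notes
    notes = list(X)
    if notes and not isinstance(notes[0], RawNote):
        # bare strings: wrap with synthetic ids
        notes = [RawNote(note_id=f"note{i:05d}", text=str(t))
                 for i, t in enumerate(notes)]
    return notes


class SymptomExtractor(BaseEstimator):
    """Rule-based multi-label classifier over clinical notes.

    Parameters mirror the pipeline's rule toggles.  ``lexicon_dir=None``
    uses the packaged default lexicons.
    """

    def __init__(self, lexicon_dir: str | None = None,
                 header_patterns_path: str | None = None,
                 require_laterality: bool = False,
                 max_pain_distance: int = 5,
                 radiation_window: int = 3,
                 checkbox_overrides_negation: bool = False,
                 historical_year_threshold: int = 1,
                 spell_max_distance: int = 1,
                 spell_min_length: int = 4,
                 apply_note_exclusions: bool = False):
        self.lexicon_dir = lexicon_dir
        self.header_patterns_path = header_patterns_path
        self.require_laterality = require_laterality
        self.max_pain_distance = max_pain_distance
        self.radiation_window = radiation_window
        self.checkbox_overrides_negation = checkbox_overrides_negation
        self.historical_year_threshold = historical_year_threshold
        self.spell_max_distance = spell_max_distance
        self.spell_min_length = spell_min_length
        self.apply_note_exclusions = apply_note_exclusions

    def fit(self, X=None, y=None) -> "SymptomExtractor":
        """Load and validate lexicons; freeze the rule configuration."""
        if self.lexicon_dir is None:
            lexicons = default_lexicons()
        else:
            lexicons = load_lexicons(self.lexicon_dir)
        report = validate_lexicons(*lexicons)
        if report["violations"]:
            raise ValueError("invalid lexicons: "
                             + "; ".join(report["violations"]))
        self.symptom_lexicons_, self.context_lexicon_ = lexicons
        self.header_patterns_ = (
            default_header_patterns()
            if self.header_patterns_path is None
            else load_header_patterns(self.header_patterns_path))
        self.symptoms_ = list(SYMPTOMS)
        self.config_ = PipelineConfig(
            require_laterality=self.require_laterality,
            max_pain_distance=self.max_pain_distance,
            radiation_window=self.radiation_window,
            checkbox_overrides_negation=self.checkbox_overrides_negation,
            historical_year_threshold=self.historical_year_threshold,
            spell_max_distance=self.spell_max_distance,
            spell_min_length=self.spell_min_length,
            exclusions=(NoteExclusions.default()
                        if self.apply_note_exclusions
                        else NoteExclusions.none()))
        return self

    def predict_notes(self, X) -> list[NoteResult]:
        """Full per-note results with sentence decisions and evidence."""
        check_is_fitted(self, "config_")
        results, _ = run_pipeline(
            _as_notes(X),
            (self.symptom_lexicons_, self.context_lexicon_),
            self.config_, self.header_patterns_)
        return results

    def predict(self, X) -> pd.DataFrame:
        """Note-by-symptom boolean DataFrame (index note_id)."""
        from .classifier import results_to_frame
        return results_to_frame(self.predict_notes(X))

    def transform(self, X) -> pd.DataFrame:
        return self.predict(X)

    def predict_note(self, note: RawNote) -> NoteResult:
        check_is_fitted(self, "config_")
        return classify_note(note, self.symptom_lexicons_,
                             self.context_lexicon_, self.config_,
                             self.header_patterns_)

    def score(self, X, y) -> float:
        """Subset accuracy against a gold note-by-symptom frame."""
        pred = self.predict(X)
        gold = y.loc[pred.index, pred.columns].astype(bool)
        return float((pred.to_numpy() == gold.to_numpy()).all(axis=1)
                     .mean())
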