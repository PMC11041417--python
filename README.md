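# pdacsym

Rule-based extraction of 17 pancreatic-ductal-adenocarcinoma (PDAC)–related
symptoms from free-text clinical notes.

Patient-reported symptoms — abdominal or epigastric pain, jaundice, weight
loss, dark urine, new-onset depression, extremity deep vein thrombosis (DVT)
and others — are often the first documented signal of pancreatic cancer, but
they live in unstructured note text rather than coded fields. `pdacsym`
implements a deterministic, auditable extraction pipeline of the kind used
for EHR-scale symptom surveillance: clinical-text normalization, sentence
splitting and tokenization, abbreviation expansion and spelling correction,
sectionization, lexicon-driven mention matching, NegEx/ConText-style context
classification, and note-level aggregation. It is aimed at clinical-NLP
researchers and informaticists who need symptom flags they can trace back to
an exact sentence, rule and cue.

Because real clinical notes are protected health data, the package also
ships a synthetic note generator that produces gold-labeled corpora covering
every rule branch, plus an evaluation harness (sensitivity, specificity,
PPV, NPV, F1, percent agreement, Cohen's kappa, categorized FP/FN reports).

## The algorithm

A symptom is decided per sentence, then aggregated per note:

1. **Mentions.** A sentence mentions a symptom if it contains a trigger
   phrase (token-sequence match, maximal matches only). Two composite rules
   go beyond single phrases: a DVT symptom requires a body-location term
   (deciding upper vs lower extremity) co-occurring with a
   feeling/appearance term, with laterality recorded when present; and
   abdominal/back pain fire when a pain word and a body-location word are
   within 5 token positions. Pain "radiating **to**" a region does not count
   as pain in that region, while pain "radiating **from**" an extremity
   still counts toward DVT.
2. **Context.** Each mention gets independent flags: negated, uncertain,
   definite, historical (history cue, or an explicit year at least one year
   before the note date), non-patient experiencer, generic/conditional
   instruction, medication-treated (in or out of hospitalization), checkbox
   affirmation, and bare checklist term. Cues scope forward within a clause,
   which distributes a cue over listed triggers ("denies nausea, vomiting,
   itching") until a scope breaker ("but", "however").
3. **Decision.** Every exclusion dominates every inclusion: a flagged
   mention (negated, uncertain, historical, non-patient,
   generic/conditional, bare, or medication-treated in hospital) is "no". A
   surviving mention is "yes" if checkbox-affirmed, in an affirming section
   (chief complaint, diagnosis — except DVT —, symptom list, history of
   present illness), medication-treated outside hospitalization, governed by
   a definite cue ("positive for", "complains of"), or an unflagged
   present-tense report. A note is positive iff at least one sentence is
   "yes"; nausea/vomiting is additionally suppressed for hospitalization
   encounters (emergency visits excepted).

Evaluation per symptom over notes: sensitivity = TP/(TP+FN),
PPV = TP/(TP+FP), specificity = TN/(TN+FP), NPV = TN/(TN+FN),
F1 = 2·PPV·sens/(PPV+sens); interrater reliability via percent agreement
and Cohen's kappa (p_o − p_e)/(1 − p_e).

All term lists are plain TSV files (`src/pdacsym/data/`) reconstructed from
published example sentences — documented, replaceable defaults rather than
any institution's internal lists.

## Worked example

```python
import datetime as dt
from pdacsym import SymptomExtractor, RawNote

extractor = SymptomExtractor().fit()
note = RawNote(
    note_id="example-1",
    note_date=dt.date(2015, 6, 1),
    encounter_type="outpatient",
    text=("Chief Complaint: abdominal pain.\n"
          "Pt denies N/V but reports 10 lb weight loss since March 2015.\n"
          "Family history: mother anxiety.\n"
          "Return if you experience yellowing of the skin."))
result = extractor.predict_note(note)
print([s for s, v in result.symptoms.items() if v])
for d in result.decisions:
    print(d.sentence_index, d.symptom_id, d.decision, d.reason_code)
```

prints

```
['abdominal_epigastric_pain', 'weight_loss']
0 abdominal_epigastric_pain yes YES_SECTION_CHIEF_COMPLAINT
1 nausea_vomiting no NO_NEGATED
1 weight_loss yes YES_SECTION_CHIEF_COMPLAINT
2 anxiety no NO_NON_PATIENT
3 jaundice no NO_GENERIC_CONDITIONAL
```

Reading the decisions: the chief-complaint header affirms abdominal pain;
"denies N/V" negates nausea/vomiting but the "but" breaks the negation
scope, so the weight-loss report is kept (and "since March 2015" marks
onset, not history); "mother anxiety" under the family-history header is
not about the patient; and the jaundice phrase inside a return-precaution
instruction is conditional, not an actual finding.
`extractor.predict(notes)` returns the note-by-symptom boolean DataFrame
for a whole corpus; the estimator follows scikit-learn conventions
(`get_params`/`set_params`/`clone`, fitted attributes with a trailing
underscore).

The same pipeline is available from the shell:

```sh
pdacsym generate --n 1000 --seed 7 --out-dir corpus/
pdacsym extract  --input corpus/ --output run/ --trace
pdacsym evaluate --gold corpus/gold_notes.csv \
                 --pred run/predictions.csv --output eval/
```

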