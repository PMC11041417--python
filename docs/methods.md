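# Methods

This note documents the extraction model, its parameters and defaults,
the synthetic-data design, numerical conventions, and the design choices
made where the problem was genuinely open.

## Text model and preprocessing

Input is one free-text clinical note (or patient message) with metadata:
note id, patient id, case/control group, note date, encounter type, note
type, department. Notes whose metadata marks them as unlikely to carry
symptom narrative (surgery encounters, patient-instruction and anesthesia
note types, health-education departments) can be filtered before
extraction; the shipped exclusion lists are deliberately minimal and
configurable.

Normalization lowercases and keeps only ASCII letters, digits, space and
the six punctuation characters `. , ? : ;`. Every other character is
deleted, joining its neighbours, with one deliberate exception: a slash
or hyphen flanked on both sides by alphanumeric runs of length ≥ 2 acts
as a separator. This keeps `vomiting/nausea`, `daughter-in-law` and
`clay-colored` as separate words (so list negation and multi-word cues
work) while fusing abbreviation shorthand (`c/o` → `co`, `n/v` → `nv`,
`x-ray` → `xray`), which the abbreviation table then expands
(`co` → "complains of", `nv` → "nausea vomiting"). Normalization is
idempotent and every retained character maps back to its raw offset, so
any token can be sliced out of the original note.

Sentences end at periods, question marks, semicolons and line breaks; a
period between two digits (decimal numbers, diagnosis codes like
`782.4`) is not a boundary. Tokens are maximal letter/digit runs; the
punctuation between tokens is retained per token for colon-sensitive
rules. Abbreviation expansion runs before spelling correction so short
forms are never "corrected". Spelling correction is deterministic
dictionary + edit distance: an out-of-dictionary, all-letter token of at
least 4 characters is replaced by its unique nearest dictionary word
within 1 edit; ties and misses leave the token unchanged (logged). The
dictionary is the union of all lexicon/cue tokens and a shipped
common-word list — an intentionally conservative, training-free stand-in
for corpus-derived misspelling lists. The 4-character floor exists
because shorter out-of-vocabulary tokens are overwhelmingly
abbreviations, where a 1-edit neighbour is usually wrong.

## Sectionization

Headers are detected from the text (structured EHR section metadata is
assumed unavailable): a sentence whose leading tokens match a header
phrase opens a section that runs to the next header or end of note, and
the header's own sentence (text after the colon) shares the label.
One-word headers (`diagnosis`, `medications`) must be followed by a
colon or stand alone on their line; multi-word headers
(`chief complaint`, `primary encounter diagnosis`) are specific enough to
open a section with same-sentence content and no colon — which is
exactly how diagnosis lines like "primary encounter diagnosis anxiety
disorder" appear in practice. Sentences before any header are `other`.

## Mention matching

* **Trigger phrases** match as token sequences (never substrings, so
  "art" cannot match inside "heart"), keeping only maximal matches per
  symptom: a match properly contained in another is collapsed into the
  longer one.
* **DVT composite rule**: a location term (deciding `dvt_lower` vs
  `dvt_upper`) and a feeling/appearance term must co-occur in the
  sentence; a laterality term is recorded when present and can be made
  mandatory (`require_laterality`, default off). The default reads the
  three term sets as location + feeling sufficing, because extremity
  swelling is routinely charted without laterality; requiring all three
  is exposed as a switch rather than hard-coded.
* **Pain proximity**: abdominal/epigastric and back pain also fire when
  a pain word and a body-location word are within `max_pain_distance`
  token positions (default 5), read as absolute difference of token
  indices within one sentence — the simplest defensible reading of a
  "5-word distance". The closest, leftmost pair is taken as the mention;
  a proximity hit overlapping a direct trigger phrase of the same
  symptom is the same locus and is merged.
* **Radiation direction**: a radiation verb (`radiating/radiates/...`)
  followed by a direction word, governing a location term within
  `radiation_window` (default 3) intervening tokens, suppresses pain
  mentions whose location is the *target* ("pain radiating to the
  back") and DVT mentions unless the extremity is the *source*
  ("radiating from the left leg"). The window bounds false scoping in
  long sentences and is configurable.

## Context flags and scope

Each mention receives independent boolean flags; no flag suppresses
another at detection time, so every detector is unit-testable and the
precedence lives in one place (the classifier). Cues scope within a
*clause*: clauses break at "but"/"however", and at a colon whose
preceding tokens end with a section-header phrase (so header words such
as "history of present illness" never act as cues for the content after
the colon). Negation, uncertainty, definiteness, present-report and
medication cues look forward only — which yields list distribution for
free ("denies A, B, C" negates all three). History, generic-instruction
and year evidence count anywhere in the clause, since phrases like "two
years ago" trail their trigger.

Historicity holds when a history cue shares the clause, or an explicit
4-digit year is at least `historical_year_threshold` (default 1)
calendar years before the note date. A year immediately preceded by
"since" marks onset of an ongoing problem ("weight loss since March
2009") and is not historical. Relative phrases ("years/months ago") are
always historical. "Hospitalization" for the medication rules and the
note-level nausea/vomiting exclusion is a configurable encounter-type
set (`hospital`, `inpatient`, `hospitalization`) that deliberately
excludes emergency visits.

## Sentence decision and aggregation

For each symptom with at least one mention, exclusions are checked first
(generic/conditional, non-patient, historical, negated, uncertain, bare
checklist term, medication-in-hospital — in that reporting order), then
inclusions (checkbox affirmation; affirming section — chief complaint,
diagnosis except DVT, symptom list, history of present illness;
outpatient medication treatment; definite cue; unflagged present-tense
report). Exclusions dominate inclusions because the underlying rule set
was tuned for precision; the published criteria do not order co-firing
yes- and no-rules, so this precedence is a declared design choice, as is
the per-mention application (a negated mention cannot be rescued by a
definite cue on the same mention, but a second, unflagged mention of the
same symptom elsewhere in the sentence still can affirm it). An opt-in
flag lets checkbox affirmation override negation inside symptom-list
sections, for checklist layouts where "no" belongs to the neighbouring
item. Symptoms never mentioned are implicitly "no".

A note is positive iff any sentence decided "yes". Decisions carry
stable reason codes (`NO_NEGATED`, `YES_SECTION_CHIEF_COMPLAINT`, ...)
so discrepancy reports are computable from provenance rather than by
re-deriving rules.

## Evaluation conventions

Metrics with zero denominators are surfaced as undefined (`None`, with a
flag) rather than coerced to 0 or 1 — on rare symptoms a fabricated
value corrupts comparisons. Percentages are reported to one decimal and
F1 to two, using half-up rounding; these are reporting conventions only,
computation is exact. Kappa uses the marginal-product expected agreement
and is undefined when expected agreement is 1; it is provided per
symptom and pooled (simple concatenation of all note × symptom pairs),
since published interrater tables do not always say which was used. The
shipped reference confusion-count table is an input for arithmetic
checks; note its nausea/vomiting row totals 927 rather than 1000 notes
because hospital-encounter notes are excluded for that symptom.

## Synthetic corpora

The generator emulates the one thing the extractor needs from real
notes: symptom phrases embedded in the contexts the rules distinguish.
Each note draws an encounter type, per-symptom positives at configurable
note-level prevalences (defaults 3–8%, pain symptoms most common, DVT
and pale stool rarest — enough positives per symptom for stable
evaluation at n ≈ 1000), a template class per symptom sentence from a
configurable mixture over 17 classes (affirmed/definite, section-headed,
checkbox, outpatient medication, radiation-from and passing-proximity on
the affirming side; negation, uncertainty, history, family, other
person, conditional instruction, bare term, in-hospital medication,
radiation-to, failing proximity and diagnosis-section DVT lines on the
non-affirming side), plus Poisson-distributed neutral distractor
sentences whose vocabulary is checked against the lexicon. Noise is a
per-sentence chance (default 4%) of a single-letter substitution inside
a symptom token, which the spelling corrector usually — not always —
repairs. Gold labels derive from template semantics alone under the same
OR-aggregation definition (with the hospital nausea exclusion); the
generator never imports the matcher or classifier, so gold and
prediction cannot collapse into one code path. Notes whose sentences
carry in-text headers are placed after all header-free sentences, each
opening its own section, so a header can never silently re-scope an
unrelated sentence's gold. For nausea-positive notes the encounter is
redrawn from the non-hospital mass, keeping prevalence targets
interpretable. Everything is driven by one seeded generator: identical
(config, seed) gives byte-identical corpora.

What passing on synthetic corpora shows — and does not. Rule-pure
corpora verify that the implementation realizes its own rule semantics
exactly (worst per-symptom F1 = 1.0); the noisy mixture additionally
exercises the correction path (F1 ≥ 0.95). Neither says how the rules
generalize to real clinical language: real notes have richer paraphrase,
misspellings beyond one edit, copy-paste structure and section layouts
the templates do not model, and published validation on real notes sits
in the 0.86–0.97 F1 range. The adversarial fixture set records known
hard cases, including two documented limitation behaviours ("lower bp"
and "patient has exhausted all conservative measures").

## Known limitations

* Default lexicons and cue lists are reconstructions from published
  examples, not a recovered study artifact; they are the replaceable
  part of the system.
* Experiencer and negation are clause-local; cross-sentence coreference
  ("she denies it") is out of scope.
* Short ambiguous shorthand ("bp") is deliberately absent from the
  lexicons, trading recall for precision.
* The checkbox marker "+" survives in the cue list for completeness but
  cannot match after normalization, which deletes it; affirmations rely
  on "yes"/"x".
* Localized itching is not distinguished from generalized pruritus.
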