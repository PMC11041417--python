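"""Canonical registry of the 17 pancreatic-cancer-related symptoms.

Symptom identifiers are stable strings used throughout the package: in
lexicon files, prediction tables, gold-label files and metric reports.
Abdominal and epigastric pain are a single combined symptom, as are
anorexia and early satiety; deep vein thrombosis (DVT) is split into
lower- and upper-extremity variants and is matched compositely rather
than by a single phrase.
"""

from __future__ import annotations

# Canonical order: gastrointestinal, systemic, mental, vascular.
SYMPTOMS: tuple[str, ...] = (
    "abdominal_epigastric_pain",
    "anorexia_early_satiety",
    "dark_urine",
    "epigastric_bloating",
    "nausea_vomiting",
    "pale_stool",
    "back_pain",
    "fatigue",
    "jaundice",
    "malaise",
    "pruritus",
    "weight_loss",
    "anxiety",
    "depression",
    "insomnia",
    "dvt_lower",
    "dvt_upper",
)

DVT_SYMPTOMS: frozenset[str] = frozenset({"dvt_lower", "dvt_upper"})

#: Symptoms located by a body region, eligible for the pain-proximity rule.
PAIN_SYMPTOMS: frozenset[str] = frozenset(
    {"abdominal_epigastric_pain", "back_pain"}
)

DISPLAY_NAMES: dict[str, str] = {
    "abdominal_epigastric_pain": "Abdominal or epigastric pain",
    "anorexia_early_satiety": "Anorexia or early satiety",
    "dark_urine": "Dark urine",
    "epigastric_bloating": "Epigastric bloating",
    "nausea_vomiting": "Nausea or vomiting",
    "pale_stool": "Pale stool",
    "back_pain": "Back pain",
    "fatigue": "Fatigue",
    "jaundice": "Jaundice",
    "malaise": "Malaise",
    "pruritus": "Pruritus",
    "weight_loss": "Weight loss",
    "anxiety": "Anxiety",
    "depression": "Depression",
    "insomnia": "Insomnia",
    "dvt_lower": "Lower extremity DVT symptom",
    "dvt_upper": "Upper extremity DVT symptom",
}


def is_symptom(symptom_id: str) -> bool:
    return symptom_id in SYMPTOMS
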