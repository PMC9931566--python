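"""Bundled vocabularies and crosswalk fixtures.

Condition identity throughout the package is the SNOMED CT-style display
name; ICD-10-CM codes are mapped onto those names with the static crosswalk
below, and distinct ICD-10-CM codes that share a display name collapse to
one condition before any counting.  The lists are editable fixtures — they
stand in for terminology services that are out of scope.

The condition list is organised into four symptom blocks (cardiopulmonary,
neurological, gastrointestinal, comorbid) plus unaffiliated background
conditions.  The synthetic generator plants its latent symptom subtypes on
these blocks, which is what makes community-detection recovery testable.
"""

from __future__ import annotations

# code of interest and its pre-release placeholder
INDEX_CODE = "U09.9"
PLACEHOLDER_CODE = "B94.8"

# block -> [(display name, [ICD-10-CM codes])]
# Dyspnea and Chest pain deliberately carry two ICD codes each so the
# many-to-one collapse is exercised by real traffic.
CONDITION_BLOCKS: dict[str, list[tuple[str, list[str]]]] = {
    "cardiopulmonary": [
        ("Dyspnea", ["R06.00", "R06.02"]),
        ("Chest pain", ["R07.9", "R07.89"]),
        ("Palpitations", ["R00.2"]),
        ("Cough", ["R05.9"]),
        ("Hypoxemia", ["R09.02"]),
        ("Atrial fibrillation", ["I48.91"]),
        ("Congestive heart failure", ["I50.9"]),
        ("Atherosclerosis", ["I70.90"]),
    ],
    "neurological": [
        ("Fatigue", ["R53.83"]),
        ("Chronic fatigue syndrome", ["R53.82"]),
        ("Headache", ["R51.9"]),
        ("Memory impairment", ["R41.3"]),
        ("Dizziness", ["R42"]),
        ("Anosmia", ["R43.0"]),
        ("Sleep disorder", ["G47.9"]),
        ("Anxiety disorder", ["F41.9"]),
    ],
    "gastrointestinal": [
        ("Abdominal pain", ["R10.9"]),
        ("Nausea", ["R11.0"]),
        ("Vomiting", ["R11.10"]),
        ("Diarrhea", ["R19.7"]),
        ("Constipation", ["K59.00"]),
        ("Gastroesophageal reflux disease", ["K21.9"]),
        ("Irritable bowel syndrome", ["K58.9"]),
        ("Loss of appetite", ["R63.0"]),
    ],
    "comorbid": [
        ("Type 2 diabetes mellitus", ["E11.9"]),
        ("Essential hypertension", ["I10"]),
        ("Hyperlipidemia", ["E78.5"]),
        ("Obesity", ["E66.9"]),
        ("Chronic kidney disease", ["N18.9"]),
        ("Hypothyroidism", ["E03.9"]),
        ("Asthma", ["J45.909"]),
        ("Chronic obstructive pulmonary disease", ["J44.9"]),
    ],
    # upper-respiratory block: unused by the default subtype mixtures for
    # adults; available for planting age-specific structure
    "upper_respiratory": [
        ("Acute pharyngitis", ["J02.9"]),
        ("Acute upper respiratory infection", ["J06.9"]),
        ("Acute sinusitis", ["J01.90"]),
        ("Otitis media", ["H66.90"]),
    ],
    "background": [
        ("Urinary tract infection", ["N39.0"]),
        ("Low back pain", ["M54.50"]),
        ("Allergic rhinitis", ["J30.9"]),
        ("Anemia", ["D64.9"]),
        ("Osteoarthritis", ["M19.90"]),
        ("Vitamin D deficiency", ["E55.9"]),
        ("Insomnia", ["G47.00"]),
        ("Dermatitis", ["L30.9"]),
    ],
}

#: display name -> block label
CONDITION_BLOCK_OF: dict[str, str] = {
    name: block
    for block, conds in CONDITION_BLOCKS.items()
    for name, _ in conds
}

#: all condition display names, in bundled order
CONDITION_NAMES: list[str] = list(CONDITION_BLOCK_OF)

#: ICD-10-CM code -> SNOMED-style display name
ICD_TO_CONDITION: dict[str, str] = {
    code: name
    for conds in CONDITION_BLOCKS.values()
    for name, codes in conds
    for code in codes
}

#: display name -> list of ICD-10-CM codes
CONDITION_TO_ICD: dict[str, list[str]] = {
    name: codes for conds in CONDITION_BLOCKS.values() for name, codes in conds
}


# ---------------------------------------------------------------------------
# procedures

#: E&M / encounter codes that only record that a visit happened (CPT).
#: Editable fixture; the operative example is office-visit code 99212.
NONINFORMATIVE_PROCEDURE_CODES: frozenset[str] = frozenset(
    {
        "99201", "99202", "99203", "99204", "99205",  # new patient office visit
        "99211", "99212", "99213", "99214", "99215",  # established patient
        "99241", "99242", "99243",                    # consultations
        "99381", "99382", "99383", "99384", "99385",  # preventive visits
        "99441", "99442", "99443",                    # telephone E&M
    }
)

#: CPT-style code -> high-level procedure category (editable fixture)
PROCEDURE_CATEGORY_OF: dict[str, str] = {
    "71045": "radiography", "71046": "radiography", "70450": "radiography",
    "74018": "radiography", "73030": "radiography",
    "93000": "electrocardiography", "93005": "electrocardiography",
    "93306": "echocardiography", "93308": "echocardiography",
    "94010": "pulmonary function testing", "94729": "pulmonary function testing",
    "97110": "physical therapy", "97112": "physical therapy",
    "97530": "occupational therapy", "97535": "occupational therapy",
    "80053": "laboratory panel", "85025": "laboratory panel",
    "36415": "venipuncture",
    "94760": "pulse oximetry",
    "93880": "vascular ultrasound",
    "92507": "speech therapy",
    "90832": "psychotherapy", "90834": "psychotherapy",
    "95810": "sleep study",
    "70551": "magnetic resonance imaging", "72148": "magnetic resonance imaging",
}

PROCEDURE_CATEGORIES: list[str] = sorted(set(PROCEDURE_CATEGORY_OF.values()))


# ---------------------------------------------------------------------------
# medications

#: ingredient -> full 7-character WHO ATC code (editable fixture).
#: Level 3 of the hierarchy is the 4-character prefix (e.g. J01CA04 -> J01C).
ATC_OF_INGREDIENT: dict[str, str] = {
    "amoxicillin": "J01CA04",
    "azithromycin": "J01FA10",
    "doxycycline": "J01AA02",
    "prednisone": "H02AB07",
    "dexamethasone": "H02AB02",
    "albuterol": "R03AC02",
    "budesonide": "R03BA02",
    "montelukast": "R03DC03",
    "guaifenesin": "R05CA03",
    "benzonatate": "R05DB01",
    "fluoxetine": "N06AB03",
    "sertraline": "N06AB06",
    "amitriptyline": "N06AA09",
    "gabapentin": "N03AX12",
    "sumatriptan": "N02CC01",
    "melatonin": "N05CH01",
    "omeprazole": "A02BC01",
    "pantoprazole": "A02BC02",
    "ondansetron": "A04AA01",
    "loperamide": "A07DA03",
    "polyethylene glycol": "A06AD15",
    "metformin": "A10BA02",
    "atorvastatin": "C10AA05",
    "lisinopril": "C09AA03",
    "metoprolol": "C07AB02",
    "ibuprofen": "M01AE01",
    "naproxen": "M01AE02",
    "acetaminophen": "N02BE01",
    "cetirizine": "R06AE07",
    "fluticasone nasal": "R01AD08",
}

INGREDIENTS: list[str] = list(ATC_OF_INGREDIENT)


def atc_level3(code: str) -> str:
    """Truncate a WHO ATC code to its level-3 (pharmacological subgroup) form,
    the 4-character prefix: one letter, two digits, one letter."""
    return code[:4]
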