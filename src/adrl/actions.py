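"""The six treatment-action classes and the medication dictionary.

Actions are integer codes 0..5.  NO_DRUGS is index 0 on purpose: it is both
the fallback action for states with no logged prescriptions and the winner
of every lowest-index tie-break, so "do nothing" is the conservative default.
"""
from __future__ import annotations

NO_DRUGS = 0
CHEI = 1
MEMANTINE = 2
CHEI_MEMANTINE = 3
ANTIHTN = 4
SUPPLEMENT = 5

N_ACTIONS = 6

ACTION_NAMES = [
    "NO_DRUGS",
    "CHEI",
    "MEMANTINE",
    "CHEI_MEMANTINE",
    "ANTIHTN",
    "SUPPLEMENT",
]

ACTION_INDEX = {name: i for i, name in enumerate(ACTION_NAMES)}

# Lowercase substring patterns -> drug class.  User-overridable: pass your own
# mapping with the same shape to map_medications_to_actions.
DEFAULT_DRUG_DICTIONARY: dict[str, tuple[str, ...]] = {
    "CHEI": (
        "donepezil",
        "aricept",
        "rivastigmine",
        "exelon",
        "galantamine",
        "razadyne",
    ),
    "MEMANTINE": ("memantine", "namenda"),
    "ANTIHTN": (
        "lisinopril",
        "enalapril",
        "ramipril",
        "losartan",
        "valsartan",
        "amlodipine",
        "metoprolol",
        "atenolol",
        "hydrochlorothiazide",
        "furosemide",
    ),
}

# Free-text entries that deliberately match none of the patterns above; the
# mapper routes them to SUPPLEMENT.
SUPPLEMENT_EXAMPLES = (
    "vitamin e",
    "vitamin b12",
    "ginkgo biloba",
    "omega-3",
    "multivitamin",
    "fish oil",
)
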