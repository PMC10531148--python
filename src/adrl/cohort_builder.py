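"""Patient selection, carry-forward imputation, action coding, cohort slicing.

The analysis cohorts layer on top of one another: the AD cohort holds
patients diagnosed with AD or MCI or prescribed AD-specific medication; the
comorbidity cohorts add hypertensive / depressed patients of any cognitive
status (including cognitively normal); the whole-data cohort keeps
everyone.  By construction AD ⊆ AD_HTN ⊆ AD_DEP_HTN and
AD ⊆ AD_DEP ⊆ AD_DEP_HTN.
"""
from __future__ import annotations

import logging

import pandas as pd

from . import actions as act
from .errors import ConfigurationError
from .state_space import DEFAULT_FEATURES

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ["MMSE", "ADAS13", "RAVLT_IMMEDIATE", "RAVLT_LEARNING", "CDRSB", "MOCA", "FDG"]

AD_DRUG_ACTIONS = {act.CHEI, act.MEMANTINE, act.CHEI_MEMANTINE}

COHORT_NAMES = ("WHOLE", "AD", "AD_HTN", "AD_DEP", "AD_DEP_HTN")


def forward_fill(visits: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Carry each patient's most recent earlier score into missing cells.

    Cells with no earlier value stay missing.  Adds one boolean
    ``<COL>_IMPUTED`` column per score recording which cells were filled.
    Idempotent: filling an already-filled table changes nothing.
    """
    if columns is None:
        columns = [c for c in SCORE_COLUMNS if c in visits.columns]
    out = visits.sort_values(["RID", "MONTH"]).reset_index(drop=True).copy()
    grouped = out.groupby("RID", sort=False)
    for col in columns:
        mask_col = f"{col}_IMPUTED"
        was_missing = out[col].isna()
        out[col] = grouped[col].ffill()
        newly_filled = was_missing & out[col].notna()
        if mask_col in out.columns:
            out[mask_col] = out[mask_col] | newly_filled
        else:
            out[mask_col] = newly_filled
    return out


def map_medications_to_actions(medications, drug_dictionary: dict | None = None) -> int:
    """One of the six action codes from a visit's free-text medication entries.

    Precedence when classes co-occur: ChEI + memantine together form the
    combination class; otherwise ChEI > memantine > antihypertensive >
    supplement.  Unrecognized entries count as supplements; an empty list is
    NO_DRUGS.
    """
    if drug_dictionary is None:
        drug_dictionary = act.DEFAULT_DRUG_DICTIONARY
    if medications is None:
        return act.NO_DRUGS
    if isinstance(medications, str):
        entries = [e for e in medications.split("|") if e.strip()]
    else:
        entries = [str(e) for e in medications if str(e).strip()]
    if not entries:
        return act.NO_DRUGS
    seen = set()
    for entry in entries:
        text = entry.lower()
        matched = None
        for klass, patterns in drug_dictionary.items():
            if any(p in text for p in patterns):
                matched = klass
                break
        seen.add(matched or "SUPPLEMENT")
    if "CHEI" in seen and "MEMANTINE" in seen:
        return act.CHEI_MEMANTINE
    for klass in ("CHEI", "MEMANTINE", "ANTIHTN", "SUPPLEMENT"):
        if klass in seen:
            return act.ACTION_INDEX[klass]
    return act.NO_DRUGS  # pragma: no cover


def assign_actions(visits: pd.DataFrame, drug_dictionary: dict | None = None) -> pd.DataFrame:
    """Add the derived integer ACTION column (total: every visit gets one code)."""
    out = visits.copy()
    out["ACTION"] = [
        map_medications_to_actions(m, drug_dictionary) for m in out["MEDICATIONS"]
    ]
    return out


def select_patients(
    visits: pd.DataFrame, required: list[str] | None = None
) -> pd.DataFrame:
    """Eligibility filter: >= 2 visits and complete records after carry-forward.

    The table is forward-filled first; patients whose required columns (the
    state-model features plus MMSE) are still incomplete at any visit — for
    example a score missing from the very first visit onward — are removed
    entirely.  Returns the filled, filtered table.
    """
    if visits.empty:
        logger.warning("select_patients: empty input table")
        return visits.copy()
    if required is None:
        required = ["MMSE"] + [f for f in DEFAULT_FEATURES if f in visits.columns and f != "AGE"]
        if "AGE" in visits.columns:
            required.append("AGE")
    filled = forward_fill(visits)
    by_patient = filled.groupby("RID")
    enough_visits = by_patient.size() >= 2
    complete = by_patient.apply(
        lambda g: not g[required].isna().any().any(), include_groups=False
    )
    keep = enough_visits & complete
    kept_ids = keep[keep].index
    n_dropped = (~keep).sum()
    if n_dropped:
        logger.info("select_patients: excluded %d of %d patients", n_dropped, len(keep))
    return filled[filled["RID"].isin(kept_ids)].reset_index(drop=True)


def _patient_flags(visits: pd.DataFrame) -> pd.DataFrame:
    """Per-patient cohort-inclusion flags from diagnoses, actions and comorbidities."""
    df = visits
    if "ACTION" not in df.columns:
        df = assign_actions(df)
    grouped = df.groupby("RID")
    is_ad = grouped.apply(
        lambda g: bool(g["DX"].isin(["AD", "MCI"]).any() or g["ACTION"].isin(AD_DRUG_ACTIONS).any()),
        include_groups=False,
    )
    is_htn = grouped["HYPERTENSION"].max().astype(bool)
    is_dep = grouped["DEPRESSION"].max().astype(bool)
    return pd.DataFrame({"is_ad": is_ad, "is_htn": is_htn, "is_dep": is_dep})


def build_cohort(visits: pd.DataFrame, cohort_name: str) -> pd.DataFrame:
    """Slice the prepared visit table to one of the five analysis cohorts."""
    if cohort_name not in COHORT_NAMES:
        raise ConfigurationError(
            f"unknown cohort {cohort_name!r}; expected one of {COHORT_NAMES}"
        )
    if cohort_name == "WHOLE":
        return visits.copy()
    flags = _patient_flags(visits)
    if cohort_name == "AD":
        keep = flags["is_ad"]
    elif cohort_name == "AD_HTN":
        keep = flags["is_ad"] | flags["is_htn"]
    elif cohort_name == "AD_DEP":
        keep = flags["is_ad"] | flags["is_dep"]
    else:  # AD_DEP_HTN
        keep = flags["is_ad"] | flags["is_htn"] | flags["is_dep"]
    kept_ids = keep[keep].index
    return visits[visits["RID"].isin(kept_ids)].reset_index(drop=True)


def prepare_visits(visits: pd.DataFrame, drug_dictionary: dict | None = None) -> pd.DataFrame:
    """Full preprocessing: eligibility + carry-forward + action coding."""
    selected = select_patients(visits)
    return assign_actions(selected, drug_dictionary)
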