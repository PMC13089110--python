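"""Amyloid classification, cohort assignment and chronological age groups.

Participants are split into an amyloid-negative cognitively-unimpaired (CU)
reference cohort and an amyloid-positive symptomatic (MCI or dementia) cohort.
Amyloid status comes from the nearest eligible PET or CSF measure within a
two-year window of the baseline MRI, with PET preferred over CSF whenever a
PET measure is available in the window.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError

#: Positivity cutoffs. PET modalities are positive at or above the cutoff
#: (SUVR, unitless); CSF Abeta-42 is positive strictly below the cutoff (pg/mL).
DEFAULT_AMYLOID_THRESHOLDS: dict[str, float] = {
    "florbetapir": 1.1,
    "PiB": 1.47,
    "CSF_abeta42": 980.0,
}

PET_MODALITIES = ("florbetapir", "PiB")
CSF_MODALITIES = ("CSF_abeta42",)

#: Chronological age-group bounds in years (inclusive on both sides).
YOUNGER_MAX_AGE = 65.0
OLDER_MIN_AGE = 80.0

AMYLOID_WINDOW_YEARS = 2.0

DIAGNOSES = ("CU", "MCI", "dementia")

AMYLOID_COLUMNS = ["participant_id", "modality", "value", "offset_years"]


def _select_measures(measures: pd.DataFrame, window_years: float) -> pd.DataFrame:
    """Pick the decisive measure per participant.

    Eligibility: |offset| <= window. PET is preferred over CSF regardless of
    recency; among PET, smallest |offset|, tie -> florbetapir, then earlier
    (smaller signed offset); same recency rule among CSF when no PET exists.
    """
    eligible = measures.loc[measures["offset_years"].abs() <= window_years].copy()
    if eligible.empty:
        return eligible
    eligible["_is_csf"] = (~eligible["modality"].isin(PET_MODALITIES)).astype(int)
    eligible["_absoff"] = eligible["offset_years"].abs()
    eligible["_mod_rank"] = (eligible["modality"] != "florbetapir").astype(int)
    ordered = eligible.sort_values(
        ["participant_id", "_is_csf", "_absoff", "_mod_rank", "offset_years"],
        kind="stable")
    return ordered.drop_duplicates("participant_id", keep="first")


def classify_amyloid(measures: pd.DataFrame,
                     thresholds: Mapping[str, float] | None = None,
                     window_years: float = AMYLOID_WINDOW_YEARS) -> pd.Series:
    """Classify amyloid status per participant from a table of measures.

    Parameters
    ----------
    measures
        Table with columns ``participant_id``, ``modality`` (``florbetapir``,
        ``PiB`` or ``CSF_abeta42``), ``value`` and ``offset_years`` (signed
        years from baseline MRI).
    thresholds
        Positivity cutoffs per modality; defaults to
        :data:`DEFAULT_AMYLOID_THRESHOLDS`. PET is positive at ``value >=
        cutoff``; CSF is positive at ``value < cutoff``.
    window_years
        Half-width of the eligibility window around the baseline MRI.

    Returns
    -------
    pandas.Series
        ``positive`` / ``negative`` / ``unknown`` per participant id, sorted
        by participant id. Participants without any measure do not appear;
        join against the participant table and fill ``unknown`` for them.
    """
    thresholds = dict(DEFAULT_AMYLOID_THRESHOLDS if thresholds is None else thresholds)
    missing_cols = [c for c in AMYLOID_COLUMNS if c not in measures.columns]
    if missing_cols:
        raise InputError(f"amyloid table missing columns: {missing_cols}")
    known = set(PET_MODALITIES) | set(CSF_MODALITIES)
    bad = sorted(set(measures["modality"]) - known)
    if bad:
        raise InputError(f"unrecognized amyloid modality values: {bad}")
    for mod in set(measures["modality"]):
        if mod not in thresholds:
            raise InputError(f"no threshold supplied for modality '{mod}'")
    chosen = _select_measures(measures, window_years)
    status = pd.Series("unknown", index=pd.Index(sorted(set(measures["participant_id"])),
                                                 name="participant_id"),
                       name="amyloid_status", dtype=object)
    if not chosen.empty:
        cutoff = chosen["modality"].map(thresholds).to_numpy(float)
        is_csf = chosen["_is_csf"].to_numpy(bool)
        value = chosen["value"].to_numpy(float)
        positive = np.where(is_csf, value < cutoff, value >= cutoff)
        status.loc[chosen["participant_id"].to_numpy()] = np.where(positive, "positive",
                                                                   "negative")
    return status


def assign_cohort(diagnosis, amyloid_status):
    """Map (diagnosis, amyloid status) to a cohort label.

    CU diagnosis with negative amyloid -> ``CU``; MCI/dementia with positive
    amyloid -> ``symptomatic``; every other combination (including unknown
    amyloid) -> ``excluded``.

    Accepts scalars or aligned pandas Series and returns the same shape.
    """
    scalar = np.isscalar(diagnosis) or isinstance(diagnosis, str)
    diag = pd.Series([diagnosis]) if scalar else pd.Series(diagnosis)
    stat = pd.Series([amyloid_status]) if scalar else pd.Series(amyloid_status)
    bad = sorted(set(diag.dropna()) - set(DIAGNOSES))
    if bad:
        raise InputError(f"unrecognized diagnosis labels: {bad}")
    cohort = pd.Series("excluded", index=diag.index, dtype=object)
    cohort[(diag == "CU") & (stat == "negative")] = "CU"
    cohort[diag.isin(["MCI", "dementia"]) & (stat == "positive")] = "symptomatic"
    return cohort.iloc[0] if scalar else cohort.rename("cohort")


def age_group(age_at_mri):
    """Assign chronological age groups: younger (<=65), older (>=80), else average."""
    scalar = np.isscalar(age_at_mri)
    age = np.asarray(age_at_mri, dtype=float)
    if np.any(~np.isfinite(age)) or np.any(age <= 0):
        raise InputError("age_at_mri must be positive and finite")
    out = np.where(age <= YOUNGER_MAX_AGE, "younger",
                   np.where(age >= OLDER_MIN_AGE, "older", "average"))
    return str(out[()]) if scalar else pd.Series(out, index=getattr(age_at_mri, "index", None),
                                                 name="age_group")


def build_cohort_table(participants: pd.DataFrame,
                       amyloid: pd.DataFrame,
                       thresholds: Mapping[str, float] | None = None,
                       window_years: float = AMYLOID_WINDOW_YEARS) -> pd.DataFrame:
    """Classify every participant: amyloid status, cohort label and age group.

    ``participants`` must carry ``id``, ``diagnosis`` and ``age_at_mri``
    columns; the result is indexed by participant id.
    """
    for col in ("id", "diagnosis", "age_at_mri"):
        if col not in participants.columns:
            raise InputError(f"participant table missing column '{col}'")
    status = classify_amyloid(amyloid, thresholds, window_years)
    table = participants.set_index("id")
    status = status.reindex(table.index).fillna("unknown")
    return pd.DataFrame({
        "amyloid_status": status,
        "cohort": assign_cohort(table["diagnosis"], status),
        "age_group": age_group(table["age_at_mri"]),
    }).rename_axis("participant_id")
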