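"""Raw registry -> analysis cohort.

Chapter filtering (ICD-10 A-N), patient-level washout exclusion, per-patient
first occurrences, and single-anchor assignment to (age decade x 2-year
calendar window) strata.  The strata partition the retained cohort, which is
what makes Cochran-Mantel-Haenszel pooling across them valid.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "filter_chapters",
    "apply_washout",
    "first_occurrences",
    "patient_profiles",
    "assign_strata",
]

ANCHOR_POLICY = "first-exposure-else-first-admission"
AGE_CONVENTION = "completed-years-midyear-birthday"

_CODE_RE = r"^[A-Z][0-9]{2}$"


def filter_chapters(events: pd.DataFrame, last_chapter: str = "N") -> pd.DataFrame:
    """Keep only level-3 codes from ICD-10 chapters A..``last_chapter``.

    Row order is preserved.  Malformed code strings raise :class:`DataError`
    naming the first offending row.
    """
    codes = events["code"].astype(str)
    ok = codes.str.match(_CODE_RE)
    if not ok.all():
        idx = int(np.flatnonzero(~ok.to_numpy())[0])
        raise DataError(f"malformed diagnosis code {codes.iloc[idx]!r} at row {idx}")
    keep = (codes.str[0] >= "A") & (codes.str[0] <= last_chapter)
    return events.loc[keep].copy()


def apply_washout(
    events: pd.DataFrame,
    washout_start: dt.date = dt.date(1997, 1, 1),
    washout_end: dt.date = dt.date(2002, 12, 31),
    observation_end: dt.date = dt.date(2014, 12, 31),
) -> pd.DataFrame:
    """Drop every patient with any admission in the washout era.

    Exclusion is all-or-nothing at the patient level; remaining events are
    restricted to admissions in (washout_end, observation_end].
    """
    adm = events["admission_date"]
    ws, we, oe = (pd.Timestamp(d) for d in (washout_start, washout_end, observation_end))
    flagged = events.loc[(adm >= ws) & (adm <= we), "patient_id"].unique()
    kept = events[~events["patient_id"].isin(flagged)]
    kept = kept[(kept["admission_date"] > we) & (kept["admission_date"] <= oe)]
    return kept.copy()


def first_occurrences(events: pd.DataFrame) -> pd.DataFrame:
    """One row per (patient, code): earliest admission carrying the code.

    Ties across same-date stays break toward the smallest stay id.  The
    operation is idempotent by construction.
    """
    ev = events.sort_values(
        ["patient_id", "code", "admission_date", "stay_id"], kind="mergesort"
    )
    fo = ev.drop_duplicates(["patient_id", "code"], keep="first")
    fo = fo[["patient_id", "code", "admission_date", "stay_id"]].rename(
        columns={"admission_date": "first_date", "stay_id": "first_stay_id"}
    )
    return fo.reset_index(drop=True)


def patient_profiles(events: pd.DataFrame) -> pd.DataFrame:
    """Per-patient sex, birth year and first admission date."""
    ev = events.sort_values(["patient_id", "admission_date"], kind="mergesort")
    prof = ev.drop_duplicates("patient_id", keep="first")[
        ["patient_id", "sex", "birth_year", "admission_date"]
    ].rename(columns={"admission_date": "first_admission"})
    return prof.reset_index(drop=True)


def _age_at(dates: pd.Series, birth_year: pd.Series) -> pd.Series:
    # completed years under a fixed July-1 birthday convention (the registry
    # carries birth year only)
    return dates.dt.year - birth_year - (dates.dt.month < 7).astype(int)


def assign_strata(
    first_occ: pd.DataFrame,
    profiles: pd.DataFrame,
    exposure_code: str = "E66",
    window_origin: int = 2003,
    min_age: int = 10,
    max_age: int = 79,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Anchor each patient once and place them in one (decade, window) cell.

    The anchor is the first occurrence of the exposure code for exposed
    patients, else the patient's first admission.  Age decade is computed at
    the anchor; patients anchored outside [min_age, max_age] are excluded
    and returned in the exclusion log.

    Returns ``(strata, exclusions)`` where ``strata`` has one row per
    retained patient (columns: patient_id, sex, exposed, anchor_date, age,
    age_decade, window) and ``exclusions`` has (patient_id, reason).
    """
    if profiles["birth_year"].isna().any():
        bad = profiles.loc[profiles["birth_year"].isna(), "patient_id"].iloc[0]
        raise DataError(f"missing birth_year for patient {bad!r}")

    exp = first_occ.loc[first_occ["code"] == exposure_code, ["patient_id", "first_date"]]
    df = profiles.merge(exp, on="patient_id", how="left")
    df["exposed"] = df["first_date"].notna()
    df["anchor_date"] = df["first_date"].fillna(df["first_admission"])
    df["age"] = _age_at(df["anchor_date"], df["birth_year"])
    df["age_decade"] = (df["age"] // 10) * 10
    df["window"] = window_origin + ((df["anchor_date"].dt.year - window_origin) // 2) * 2

    in_range = (df["age"] >= min_age) & (df["age"] <= max_age)
    exclusions = pd.DataFrame(
        {
            "patient_id": df.loc[~in_range, "patient_id"],
            "reason": "anchor_age_out_of_range",
        }
    ).reset_index(drop=True)
    strata = df.loc[
        in_range,
        ["patient_id", "sex", "exposed", "anchor_date", "age", "age_decade", "window"],
    ].reset_index(drop=True)
    return strata, exclusions
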