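"""Sex-stratified runs, sex-specific odds ratios, and the somatic-exclusion
sensitivity analysis.

``sex_stratified_run`` repeats the association screen within one sex.
``sex_specific_or`` flips the question around inside the exposed cohort:
among exposed patients of one age decade, how much more likely is a given
comorbidity in women than in men (female odds in the numerator), pooled
over 2-year windows with the same Mantel-Haenszel machinery as the main
screen.  ``sensitivity_exclude`` removes — patient-level and idempotent —
everyone ever carrying one of a set of somatic codes (default diabetes E11,
hypertension I10, coronary artery disease I25) so the screen can be re-run
without those known risk carriers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .association import CMHResult, MHResult, cmh_test, mantel_haenszel_or, screen_pairs
from .errors import DataError

__all__ = [
    "SexOrResult",
    "sex_stratified_run",
    "sex_specific_or",
    "sensitivity_exclude",
    "DEFAULT_SENSITIVITY_CODES",
]

DEFAULT_SENSITIVITY_CODES: frozenset[str] = frozenset({"E11", "I10", "I25"})


@dataclass(frozen=True)
class SexOrResult:
    """Female-vs-male odds ratio for one comorbidity within exposed patients."""

    code: str
    age_decade: object
    or_female_vs_male: float
    ci_low: float
    ci_high: float
    p_raw: float
    n_female: int
    n_male: int
    defined: bool


def sex_stratified_run(
    first_occ: pd.DataFrame,
    strata: pd.DataFrame,
    sex: str,
    exposure_code: str,
    comorbidity_codes: Sequence[str],
    **screen_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Association screen restricted to one sex; results carry a sex tag."""
    if sex not in ("female", "male"):
        raise DataError(f"unknown sex {sex!r}")
    sub = strata[strata["sex"] == sex]
    if sub.empty:
        raise DataError(f"no patients with sex={sex!r} in the cohort")
    results, meta = screen_pairs(
        first_occ, sub, exposure_code, comorbidity_codes, **screen_kwargs
    )
    results = results.copy()
    results.insert(0, "sex", sex)
    meta = dict(meta, sex=sex)
    return results, meta


def sex_specific_or(
    first_occ: pd.DataFrame,
    strata: pd.DataFrame,
    comorbidity: str,
    age_decade: int,
) -> SexOrResult:
    """Female-vs-male OR for a comorbidity among exposed patients of a decade.

    Builds per-window 2x2 tables of sex x comorbidity presence over exposed
    patients anchored in the decade and pools them with the MH estimator;
    zero-cell degeneracy yields the usual sentinel (``defined=False``).
    """
    sub = strata[(strata["exposed"]) & (strata["age_decade"] == age_decade)]
    if sub.empty:
        raise DataError(f"no exposed patients in decade {age_decade}")
    has = sub["patient_id"].isin(
        first_occ.loc[first_occ["code"] == comorbidity, "patient_id"]
    ).to_numpy()
    female = (sub["sex"] == "female").to_numpy()
    df = pd.DataFrame({"window": sub["window"].to_numpy(), "F": female, "H": has})
    counts = df.groupby(["window", "F", "H"]).size().unstack(["F", "H"], fill_value=0)

    def col(key):
        return counts[key].to_numpy(dtype=float) if key in counts.columns else np.zeros(len(counts))

    a = col((True, True))    # female with comorbidity
    b = col((True, False))   # female without
    c = col((False, True))   # male with
    d = col((False, False))  # male without
    mh: MHResult = mantel_haenszel_or((a, b, c, d))
    test: CMHResult = cmh_test((a, b, c, d))
    return SexOrResult(
        code=comorbidity,
        age_decade=age_decade,
        or_female_vs_male=mh.or_mh,
        ci_low=mh.ci_low,
        ci_high=mh.ci_high,
        p_raw=test.p_value,
        n_female=int(female.sum()),
        n_male=int((~female).sum()),
        defined=mh.defined,
    )


def sensitivity_exclude(
    events: pd.DataFrame,
    excluded_codes: Iterable[str] = DEFAULT_SENSITIVITY_CODES,
) -> pd.DataFrame:
    """Drop every patient ever carrying one of ``excluded_codes``.

    Patient-level (all rows of a flagged patient go) and idempotent.  An
    empty exclusion set is a warned no-op.
    """
    excluded = set(excluded_codes)
    if not excluded:
        warnings.warn("sensitivity_exclude called with an empty code set; no-op")
        return events.copy()
    flagged = events.loc[events["code"].isin(excluded), "patient_id"].unique()
    return events[~events["patient_id"].isin(flagged)].copy()
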