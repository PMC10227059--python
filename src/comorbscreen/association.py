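"""Stratified 2x2 association screening.

For each (exposure, comorbidity) pair the retained cohort is cross-tabulated
within every (age decade, 2-year window) stratum, and strata are pooled with
the Mantel-Haenszel common odds ratio

    OR_MH = sum_i(a_i d_i / n_i) / sum_i(b_i c_i / n_i)

with a 95% CI from the Robins-Breslow-Greenland (RBG) variance of
log(OR_MH).  Association is tested with the Cochran-Mantel-Haenszel (CMH)
chi-square statistic (1 df, no continuity correction)

    X^2 = (sum_i a_i - sum_i E_i)^2 / sum_i V_i,

E_i and V_i being the hypergeometric mean and variance of the a-cell under
fixed margins.  Screening applies a minimum co-occurrence filter, Bonferroni
correction over the surviving tests, and the OR > threshold conjunction.

Zero-denominator estimates return an infinite/undefined sentinel (never a
crash); degenerate strata contribute nothing to the CMH statistic and are
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

__all__ = [
    "StratumTable",
    "ContingencySeries",
    "MHResult",
    "CMHResult",
    "build_contingency_series",
    "pair_tables",
    "mantel_haenszel_or",
    "cmh_test",
    "crude_or",
    "screen_associations",
    "screen_pairs",
]


@dataclass(frozen=True)
class StratumTable:
    """One 2x2 table: a = exposed-with, b = exposed-without,
    c = unexposed-with, d = unexposed-without."""

    window: object
    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class ContingencySeries:
    """Disjoint per-window 2x2 tables for one pair within one age group."""

    code_a: str
    code_b: str
    age_decade: object
    tables: list[StratumTable] = field(default_factory=list)

    def counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        a = np.array([t.a for t in self.tables], dtype=float)
        b = np.array([t.b for t in self.tables], dtype=float)
        c = np.array([t.c for t in self.tables], dtype=float)
        d = np.array([t.d for t in self.tables], dtype=float)
        return a, b, c, d


class MHResult(NamedTuple):
    or_mh: float
    ci_low: float
    ci_high: float
    se_log: float
    defined: bool


class CMHResult(NamedTuple):
    statistic: float
    p_value: float
    n_strata_used: int
    degenerate: bool


def _counts(series) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(series, ContingencySeries):
        return series.counts()
    a, b, c, d = (np.asarray(x, dtype=float) for x in series)
    if a.size == 0:
        raise DataError("empty contingency series")
    if min(a.min(), b.min(), c.min(), d.min()) < 0:
        raise DataError("negative cell count in contingency series")
    return a, b, c, d


def mantel_haenszel_or(series) -> MHResult:
    """Mantel-Haenszel pooled OR with the RBG 95% confidence interval.

    ``series`` is a :class:`ContingencySeries` or an ``(a, b, c, d)`` tuple
    of per-stratum arrays.  A zero pooled denominator (or numerator) yields
    an inf/0/NaN sentinel with ``defined=False`` instead of an exception.
    """
    a, b, c, d = _counts(series)
    n = a + b + c + d
    with np.errstate(invalid="ignore", divide="ignore"):
        R_i = np.where(n > 0, a * d / n, 0.0)
        S_i = np.where(n > 0, b * c / n, 0.0)
    R, S = R_i.sum(), S_i.sum()
    if R == 0.0 and S == 0.0:
        return MHResult(np.nan, np.nan, np.nan, np.nan, False)
    if S == 0.0:
        return MHResult(np.inf, np.nan, np.nan, np.nan, False)
    if R == 0.0:
        return MHResult(0.0, np.nan, np.nan, np.nan, False)
    or_mh = R / S
    with np.errstate(invalid="ignore", divide="ignore"):
        P_i = np.where(n > 0, (a + d) / n, 0.0)
        Q_i = np.where(n > 0, (b + c) / n, 0.0)
    var = (
        (P_i * R_i).sum() / (2.0 * R * R)
        + ((P_i * S_i + Q_i * R_i)).sum() / (2.0 * R * S)
        + (Q_i * S_i).sum() / (2.0 * S * S)
    )
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    log_or = np.log(or_mh)
    return MHResult(
        float(or_mh),
        float(np.exp(log_or - z * se)),
        float(np.exp(log_or + z * se)),
        se,
        True,
    )


def cmh_test(series) -> CMHResult:
    """CMH chi-square test of conditional association (1 df, uncorrected).

    Strata with n <= 1 or a zero margin carry no information about the
    common OR; they are dropped and flagged via ``degenerate`` when all
    strata drop out (then p = 1 by convention).
    """
    a, b, c, d = _counts(series)
    n = a + b + c + d
    r1, r0 = a + b, c + d
    c1, c0 = a + c, b + d
    ok = (n > 1) & (r1 > 0) & (r0 > 0) & (c1 > 0) & (c0 > 0)
    if not ok.any():
        return CMHResult(0.0, 1.0, 0, True)
    a, n, r1, r0, c1, c0 = (x[ok] for x in (a, n, r1, r0, c1, c0))
    E = r1 * c1 / n
    V = r1 * r0 * c1 * c0 / (n * n * (n - 1.0))
    Vsum = V.sum()
    if Vsum == 0.0:
        return CMHResult(0.0, 1.0, int(ok.sum()), True)
    statistic = float((a.sum() - E.sum()) ** 2 / Vsum)
    p = float(stats.chi2.sf(statistic, df=1))
    return CMHResult(statistic, p, int(ok.sum()), False)


def crude_or(series) -> float:
    """Unstratified (collapsed) odds ratio — the confounded comparator."""
    a, b, c, d = _counts(series)
    num, den = a.sum() * d.sum(), b.sum() * c.sum()
    if den == 0.0:
        return np.inf if num > 0 else np.nan
    return float(num / den)


def pair_tables(
    strata: pd.DataFrame,
    first_occ: pd.DataFrame,
    code_a: str,
    code_b: str,
) -> pd.DataFrame:
    """Per-(decade, window) 2x2 counts for one diagnosis pair.

    Presence of a code = any first occurrence during the observation era.
    Cells with zero patients are absent from the result, so each row is a
    genuine stratum.  Returns a frame indexed by (age_decade, window) with
    columns a, b, c, d.
    """
    if code_a == code_b:
        raise ConfigError("a diagnosis pair needs two distinct codes")
    has_a = strata["patient_id"].isin(
        first_occ.loc[first_occ["code"] == code_a, "patient_id"]
    )
    has_b = strata["patient_id"].isin(
        first_occ.loc[first_occ["code"] == code_b, "patient_id"]
    )
    df = pd.DataFrame(
        {
            "age_decade": strata["age_decade"].to_numpy(),
            "window": strata["window"].to_numpy(),
            "A": has_a.to_numpy(),
            "B": has_b.to_numpy(),
        }
    )
    counts = df.groupby(["age_decade", "window", "A", "B"], sort=True).size()
    tab = counts.unstack(["A", "B"], fill_value=0)
    out = pd.DataFrame(index=tab.index)
    for name, key in (("a", (True, True)), ("b", (True, False)),
                      ("c", (False, True)), ("d", (False, False))):
        out[name] = tab[key] if key in tab.columns else 0
    return out


def build_contingency_series(
    strata: pd.DataFrame,
    first_occ: pd.DataFrame,
    code_a: str,
    code_b: str,
    age_decade: int,
) -> ContingencySeries:
    """ContingencySeries for one pair within one age decade."""
    tabs = pair_tables(strata, first_occ, code_a, code_b)
    series = ContingencySeries(code_a, code_b, age_decade)
    if age_decade in tabs.index.get_level_values("age_decade"):
        sub = tabs.xs(age_decade, level="age_decade")
        for window, row in sub.iterrows():
            series.tables.append(
                StratumTable(window, int(row.a), int(row.b), int(row.c), int(row.d))
            )
    return series


def screen_associations(
    drafts: pd.DataFrame,
    m: int | None = None,
    min_occurrence: int = 100,
    or_threshold: float = 1.5,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Apply the occurrence filter, Bonferroni correction and significance rule.

    ``drafts`` needs columns ``age_decade, or_mh, p_raw, n_cooccur``.  Pairs
    under ``min_occurrence`` co-occurrences are marked ``filtered`` and do
    not count toward the Bonferroni family ``m`` (pooled 'total' summary rows
    are corrected but excluded from ``m`` as well).  ``significant`` is the
    conjunction OR > or_threshold AND p_corr < alpha AND the filter.
    """
    out = drafts.copy()
    out["filtered"] = out["n_cooccur"] < min_occurrence
    in_family = (~out["filtered"]) & (out["age_decade"] != "total")
    if m is None:
        m = int(in_family.sum())
    if m <= 0:
        raise DataError("no tests survive the occurrence filter (m <= 0)")
    out["p_corr"] = np.where(
        out["filtered"], np.nan, np.minimum(1.0, out["p_raw"] * m)
    )
    out["significant"] = (
        (~out["filtered"])
        & (out["or_mh"] > or_threshold)
        & (out["p_corr"] < alpha)
    )
    meta = {
        "m": m,
        "min_occurrence": min_occurrence,
        "or_threshold": or_threshold,
        "alpha": alpha,
    }
    return out, meta


def screen_pairs(
    first_occ: pd.DataFrame,
    strata: pd.DataFrame,
    exposure_code: str,
    comorbidity_codes: Sequence[str],
    min_occurrence: int = 100,
    or_threshold: float = 1.5,
    alpha: float = 0.01,
    include_total: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Full association screen of the exposure against each comorbidity.

    Emits one draft row per (pair, age decade) plus an optional pooled
    'total' row per pair (all decade x window strata pooled), then applies
    :func:`screen_associations`.  Rates are co-diagnosis percentages among
    exposed / unexposed patients in the group.
    """
    rows = []
    for code in comorbidity_codes:
        tabs = pair_tables(strata, first_occ, exposure_code, code)
        groups: list[tuple[object, pd.DataFrame]] = [
            (dec, sub.droplevel("age_decade"))
            for dec, sub in tabs.groupby(level="age_decade")
        ]
        if include_total:
            groups.append(("total", tabs))
        for decade, sub in groups:
            arrs = (sub["a"].to_numpy(), sub["b"].to_numpy(),
                    sub["c"].to_numpy(), sub["d"].to_numpy())
            mh = mantel_haenszel_or(arrs)
            test = cmh_test(arrs)
            n_exp = float(arrs[0].sum() + arrs[1].sum())
            n_unexp = float(arrs[2].sum() + arrs[3].sum())
            rows.append(
                {
                    "code_a": exposure_code,
                    "code_b": code,
                    "age_decade": decade,
                    "or_mh": mh.or_mh,
                    "ci_low": mh.ci_low,
                    "ci_high": mh.ci_high,
                    "p_raw": test.p_value,
                    "n_cooccur": int(arrs[0].sum()),
                    "rate_exposed_pct": 100.0 * arrs[0].sum() / n_exp if n_exp else np.nan,
                    "rate_unexposed_pct": 100.0 * arrs[2].sum() / n_unexp if n_unexp else np.nan,
                    "or_defined": mh.defined,
                    "cmh_degenerate": test.degenerate,
                }
            )
    drafts = pd.DataFrame(rows)
    return screen_associations(
        drafts, m=None, min_occurrence=min_occurrence,
        or_threshold=or_threshold, alpha=alpha,
    )
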