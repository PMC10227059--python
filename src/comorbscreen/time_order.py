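"""Time-order (directionality) analysis of diagnosis pairs.

For every patient carrying both diagnoses of a pair, the first-occurrence
dates define a direction (A first, B first, or a tie when both codes were
received at one hospital stay or on the same day).  Patients are grouped by
the gap between diagnoses into four classes — same stay, up to ~1 year
(360 days), 1-3 years (361-1080 days), beyond 3 years — and per class the
time-order ratio

    TOR(A -> B) = N(A first) / N(B first)

is reported together with an exact two-sided binomial sign test of
N(A first) = N(B first).  TOR > 1 means A tends to be diagnosed first.
Ties are counted and reported but enter neither the ratio nor the test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "OrderedPair",
    "GAP_CLASSES",
    "DEFAULT_GAP_EDGES",
    "ordered_pairs",
    "classify_gap",
    "compute_tor",
    "binomial_sign_test",
]

#: canonical class labels for the default edges (360, 1080)
GAP_CLASSES: tuple[str, ...] = ("same_stay", "lt_1y", "1y_to_3y", "gt_3y")

#: the 360-day year convention: <=360 days ~ "within a year", 3*360 = 1080
DEFAULT_GAP_EDGES: tuple[int, ...] = (360, 1080)


@dataclass(frozen=True)
class OrderedPair:
    """First-occurrence ordering of one diagnosis pair for one patient."""

    patient_id: object
    date_a: pd.Timestamp
    date_b: pd.Timestamp
    same_stay: bool

    @property
    def gap_days(self) -> int:
        return abs((pd.Timestamp(self.date_b) - pd.Timestamp(self.date_a)).days)

    @property
    def direction(self) -> str:
        if self.same_stay or self.date_a == self.date_b:
            return "tie"
        return "A_first" if pd.Timestamp(self.date_a) < pd.Timestamp(self.date_b) else "B_first"


def _pairs_frame(pairs) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        return pairs
    rows = [
        {
            "patient_id": p.patient_id,
            "same_stay": p.same_stay,
            "gap_days": p.gap_days,
            "direction": p.direction,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows)


def ordered_pairs(
    first_occ: pd.DataFrame, code_a: str, code_b: str
) -> pd.DataFrame:
    """Ordered-pair table for all patients carrying both codes.

    ``same_stay`` means both first occurrences share a stay id; equal dates
    on distinct stays also yield a tie (no defensible order).
    """
    fa = first_occ.loc[first_occ["code"] == code_a,
                       ["patient_id", "first_date", "first_stay_id"]]
    fb = first_occ.loc[first_occ["code"] == code_b,
                       ["patient_id", "first_date", "first_stay_id"]]
    df = fa.merge(fb, on="patient_id", suffixes=("_a", "_b"))
    if df.empty:
        return pd.DataFrame(
            columns=["patient_id", "date_a", "date_b", "same_stay", "gap_days", "direction"]
        )
    df = df.rename(columns={"first_date_a": "date_a", "first_date_b": "date_b"})
    df["same_stay"] = df["first_stay_id_a"] == df["first_stay_id_b"]
    gap = (df["date_b"] - df["date_a"]).dt.days
    if (gap.abs() < 0).any():  # pragma: no cover - defensive
        raise DataError("negative absolute gap")
    df["gap_days"] = gap.abs()
    df["direction"] = np.where(
        df["same_stay"] | (gap == 0), "tie", np.where(gap > 0, "A_first", "B_first")
    )
    return df[["patient_id", "date_a", "date_b", "same_stay", "gap_days", "direction"]]


def classify_gap(
    gap_days: np.ndarray | Sequence[int],
    same_stay: np.ndarray | Sequence[bool],
    edges: Sequence[int] = DEFAULT_GAP_EDGES,
) -> np.ndarray:
    """Assign each pair to a gap class; boundary days go to the lower class.

    ``edges`` is a strictly ascending day list; the defaults reproduce the
    four canonical classes.  Custom edges yield generated labels
    ``le_<e1>, <e1+1>_to_<e2>, ..., gt_<ek>``.
    """
    edges = tuple(int(e) for e in edges)
    if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])) or (edges and edges[0] < 1):
        raise DataError("gap class edges must be strictly ascending positive days")
    gap = np.asarray(gap_days, dtype=float)
    if (gap < 0).any():
        raise DataError("negative gap_days")
    if tuple(edges) == DEFAULT_GAP_EDGES:
        labels = list(GAP_CLASSES[1:])
    else:
        labels = [f"le_{edges[0]}"]
        labels += [f"{e1 + 1}_to_{e2}" for e1, e2 in zip(edges, edges[1:])]
        labels += [f"gt_{edges[-1]}"]
    idx = np.searchsorted(np.asarray(edges, dtype=float), gap, side="left")
    out = np.asarray(labels, dtype=object)[idx]
    out = np.where(np.asarray(same_stay, dtype=bool), "same_stay", out)
    return out


def binomial_sign_test(n_a_first: int, n_b_first: int) -> float:
    """Exact two-sided binomial test of equal direction counts.

    p = min(1, 2 * min(P(X <= k), P(X >= k))) with X ~ Binomial(n, 1/2),
    n = n_a_first + n_b_first, k = n_a_first.
    """
    k, nb = int(n_a_first), int(n_b_first)
    if k < 0 or nb < 0:
        raise DataError("direction counts must be non-negative")
    n = k + nb
    if n == 0:
        raise DataError("binomial sign test needs at least one ordered pair")
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def compute_tor(
    pairs: pd.DataFrame | Iterable[OrderedPair],
    edges: Sequence[int] = DEFAULT_GAP_EDGES,
    profiles: pd.DataFrame | None = None,
    by_sex: bool = False,
) -> pd.DataFrame:
    """Per-gap-class direction counts, TOR and binomial p for one pair.

    Emits one row per gap class (zero classes included so group shares sum
    to 100%) plus an ``all`` row pooling every class.  With ``by_sex=True``
    (requires ``profiles`` with patient_id/sex) the grouping is additionally
    per sex, shares computed within sex.  ``tor`` is ``inf`` when no B-first
    patients exist and ``NaN`` when no ordered patients exist; ``p_binomial``
    is ``NaN`` without ordered patients.
    """
    df = _pairs_frame(pairs).copy()
    if by_sex:
        if profiles is None:
            raise DataError("by_sex=True requires patient profiles")
        df = df.merge(profiles[["patient_id", "sex"]], on="patient_id", how="left")
        sex_groups = [s for s in ("female", "male") if (df["sex"] == s).any()]
    else:
        df["sex"] = "all"
        sex_groups = ["all"]

    if df.empty:
        classes = list(GAP_CLASSES) if tuple(edges) == DEFAULT_GAP_EDGES else []
        return pd.DataFrame(
            columns=["sex", "gap_class", "n_a_first", "n_b_first", "n_tie",
                     "tor", "p_binomial", "group_share_pct"]
        )

    df["gap_class"] = classify_gap(df["gap_days"].to_numpy(),
                                   df["same_stay"].to_numpy(), edges)
    if tuple(edges) == DEFAULT_GAP_EDGES:
        class_order = list(GAP_CLASSES)
    else:
        seen = classify_gap([0, *edges, edges[-1] + 1], [True] + [False] * (len(edges) + 1), edges)
        class_order = list(dict.fromkeys(seen))

    rows = []
    for sex in sex_groups:
        sub = df[df["sex"] == sex]
        total = len(sub)
        for cls in [*class_order, "all"]:
            grp = sub if cls == "all" else sub[sub["gap_class"] == cls]
            na = int((grp["direction"] == "A_first").sum())
            nb = int((grp["direction"] == "B_first").sum())
            nt = int((grp["direction"] == "tie").sum())
            if na + nb == 0:
                tor, p = np.nan, np.nan
            else:
                tor = float(na) / nb if nb > 0 else np.inf
                p = binomial_sign_test(na, nb)
            share = 100.0 * len(grp) / total if cls != "all" else 100.0
            rows.append(
                {
                    "sex": sex,
                    "gap_class": cls,
                    "n_a_first": na,
                    "n_b_first": nb,
                    "n_tie": nt,
                    "tor": tor,
                    "p_binomial": p,
                    "group_share_pct": share,
                }
            )
    return pd.DataFrame(rows)
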