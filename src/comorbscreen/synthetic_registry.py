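"""Synthetic longitudinal inpatient registry with known injected effects.

The generator emulates the structure of a national hospital-stay registry:
one row per (patient, stay, level-3 ICD-10 diagnosis), with sex, birth year
and admission/release dates, spanning 1997-2014.  Two ground-truth effects
are injected and can later be recovered by the analysis modules:

* ``theta`` — a common odds multiplier: within every (age decade, 2-year
  calendar window) stratum the odds of each comorbidity given the exposure
  diagnosis are ``theta`` times the baseline odds, so the Mantel-Haenszel
  common-odds-ratio assumption holds exactly by construction.
* ``rho`` — a direction bias: among dual-diagnosed patients whose two
  diagnoses are not coded at the same stay, the exposure is diagnosed first
  with probability ``rho / (1 + rho)``, i.e. the population time-order
  ratio equals ``rho`` in every gap class.

Randomness is consumed from a single PCG64 stream in a fixed per-patient
column layout (row-major), so regenerating with a larger ``n_patients`` and
the same seed reproduces the first patients byte-identically.
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy import stats

from .errors import ConfigError

__all__ = [
    "GapMixture",
    "GeneratorConfig",
    "generate_registry",
    "confounded_scenario",
]

#: age decades covered by the analysis (lower bounds of 10-19 ... 70-79)
DECADES: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70)

SEXES: tuple[str, str] = ("female", "male")

_EPOCH = np.datetime64("1970-01-01")


def _day(d: dt.date) -> int:
    """Calendar date -> integer days since epoch (vector-friendly anchor)."""
    return int((np.datetime64(d) - _EPOCH).astype("timedelta64[D]").astype(int))


class GapMixture(BaseModel):
    """Mixture of uniform day-ranges for the gap between paired diagnoses.

    Ranges are inclusive, strictly positive, ascending and non-overlapping;
    the defaults target the analysis' four gap classes (same stay handled
    separately via ``p_same_stay``).
    """

    model_config = ConfigDict(frozen=True)

    weights: tuple[float, ...] = (0.45, 0.30, 0.25)
    ranges: tuple[tuple[int, int], ...] = ((1, 360), (361, 1080), (1081, 2400))

    @model_validator(mode="after")
    def _check(self) -> "GapMixture":
        if len(self.weights) != len(self.ranges) or not self.weights:
            raise ConfigError("gap_mixture weights and ranges must have equal, nonzero length")
        if any(w < 0 for w in self.weights) or sum(self.weights) <= 0:
            raise ConfigError("gap_mixture weights must be non-negative with positive sum")
        prev_hi = 0
        for lo, hi in self.ranges:
            if lo < 1 or hi < lo:
                raise ConfigError(f"gap range ({lo}, {hi}) must satisfy 1 <= lo <= hi")
            if lo <= prev_hi:
                raise ConfigError("gap ranges must be ascending and non-overlapping")
            prev_hi = hi
        return self

    def cumulative_weights(self) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        return np.cumsum(w) / w.sum()


# default filler-code pools; deliberately disjoint from the analysis codes
_DEFAULT_NOISE = ("A09", "B99", "C44", "D12", "G43", "H25", "J18", "K29", "L40", "M54", "N39")
_DEFAULT_OZ = ("O80", "P07", "Q21", "R10", "S06", "T78", "Z38")


class GeneratorConfig(BaseModel):
    """All knobs of the synthetic registry.

    ``baseline_prevalence`` maps each code to either a scalar (flat), a
    7-vector (per age decade), or a 7x2 nested list (decade x [female, male])
    probability of ever receiving the diagnosis during the observation era.
    ``theta`` may be a scalar or a ``{"female": f, "male": m}`` mapping.
    """

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(gt=0)
    period_start: dt.date = dt.date(1997, 1, 1)
    period_end: dt.date = dt.date(2014, 12, 31)
    observation_start: dt.date = dt.date(2003, 1, 1)
    washout_fraction: float = Field(default=0.2, ge=0.0, le=1.0)
    mean_stays: float = Field(default=2.0, gt=0.0)
    mean_stay_days: float = Field(default=4.0, gt=0.0)
    baseline_prevalence: Mapping[str, float | Sequence[float] | Sequence[Sequence[float]]]
    exposure_code: str = "E66"
    comorbidity_codes: tuple[str, ...] = ("F32",)
    theta: float | Mapping[str, float] = 1.0
    rho: float = Field(default=1.0, ge=0.0)
    p_same_stay: float = Field(default=0.25, ge=0.0, le=1.0)
    gap_mixture: GapMixture = GapMixture()
    sex_ratio: float = Field(default=0.5, ge=0.0, le=1.0)
    noise_codes: tuple[str, ...] = _DEFAULT_NOISE
    oz_codes: tuple[str, ...] = _DEFAULT_OZ
    oz_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    max_extra_stays: int = Field(default=8, ge=0)
    seed: int = 0

    @field_validator("exposure_code")
    @classmethod
    def _code_shape(cls, v: str) -> str:
        if len(v) != 3 or not v[0].isupper() or not v[1:].isdigit():
            raise ConfigError(f"malformed ICD-3 code {v!r}")
        return v

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if not (self.period_start <= self.observation_start <= self.period_end):
            raise ConfigError("require period_start <= observation_start <= period_end")
        for code in (*self.comorbidity_codes, *self.noise_codes, *self.oz_codes):
            if len(code) != 3 or not code[0].isupper() or not code[1:].isdigit():
                raise ConfigError(f"malformed ICD-3 code {code!r}")
        if self.exposure_code in self.comorbidity_codes:
            raise ConfigError("exposure_code must not appear in comorbidity_codes")
        special = {self.exposure_code, *self.comorbidity_codes}
        if special & set(self.noise_codes) or special & set(self.oz_codes):
            raise ConfigError("noise code pools must be disjoint from analysis codes")
        for code in (self.exposure_code, *self.comorbidity_codes):
            if code not in self.baseline_prevalence:
                raise ConfigError(f"baseline_prevalence missing entry for {code}")
        tf, tm = self.theta_by_sex()
        if tf < 0 or tm < 0:
            raise ConfigError("theta must be >= 0")
        # feasibility of the odds-scale inflation in every stratum
        for code in self.comorbidity_codes:
            prev = self.prevalence_array(code)
            for di, dec in enumerate(DECADES):
                for si, sex in enumerate(SEXES):
                    p = prev[di, si]
                    th = tf if sex == "female" else tm
                    p_inf = _inflate_odds(p, th)
                    if p >= 1.0 or p_inf >= 1.0:
                        raise ConfigError(
                            f"theta-inflated prevalence for {code} reaches 1 in "
                            f"stratum (decade {dec}-{dec + 9}, {sex})"
                        )
        self.prevalence_array(self.exposure_code)  # validates shape/bounds
        return self

    def prevalence_array(self, code: str) -> np.ndarray:
        """Return the (7 decades x 2 sexes) prevalence matrix for ``code``."""
        raw = self.baseline_prevalence[code]
        if np.isscalar(raw):
            arr = np.full((len(DECADES), 2), float(raw))
        else:
            arr = np.asarray(raw, dtype=float)
            if arr.shape == (len(DECADES),):
                arr = np.repeat(arr[:, None], 2, axis=1)
            elif arr.shape != (len(DECADES), 2):
                raise ConfigError(
                    f"prevalence for {code} must be scalar, length-{len(DECADES)}, "
                    f"or {len(DECADES)}x2; got shape {arr.shape}"
                )
        if (arr < 0).any() or (arr > 1).any():
            raise ConfigError(f"prevalence for {code} outside [0, 1]")
        return arr

    def theta_by_sex(self) -> tuple[float, float]:
        if isinstance(self.theta, Mapping):
            try:
                return float(self.theta["female"]), float(self.theta["male"])
            except KeyError as exc:  # pragma: no cover - config error path
                raise ConfigError("per-sex theta needs 'female' and 'male' keys") from exc
        return float(self.theta), float(self.theta)

    def window_starts(self) -> list[int]:
        """Start years of the 2-year calendar windows in the observation era."""
        return list(range(self.observation_start.year, self.period_end.year + 1, 2))


def _inflate_odds(p: float, theta: float) -> float:
    """Scalar odds multiplier: p -> theta*odds(p) / (1 + theta*odds(p))."""
    if p >= 1.0:
        return 1.0
    to = theta * (p / (1.0 - p))
    return to / (1.0 + to)


def confounded_scenario(config: GeneratorConfig) -> GeneratorConfig:
    """Return a copy of ``config`` with age-confounded prevalence maps.

    Both the exposure and every comorbidity become more prevalent with age
    decade (0.05 ... 0.35, linear) while ``theta`` is untouched, so the crude
    (unstratified) OR is biased upward away from ``theta`` but the
    age-stratified Mantel-Haenszel OR is not.  Only the prevalence maps
    differ from the input config.
    """
    gradient = [0.05 + 0.05 * i for i in range(len(DECADES))]
    prev = {code: gradient for code in (config.exposure_code, *config.comorbidity_codes)}
    return config.model_copy(update={"baseline_prevalence": prev})


# ---------------------------------------------------------------------------
# per-patient uniform-draw column layout (fixed => prefix-stable in n)
# ---------------------------------------------------------------------------
_COL_SEX = 0
_COL_DECADE = 1
_COL_WINDOW = 2
_COL_AGE = 3
_COL_ANCHOR = 4
_COL_ANCHOR_LEN = 5
_COL_WASH_FLAG = 6
_COL_WASH_DAY = 7
_COL_WASH_LEN = 8
_COL_NSTAYS = 9
_COL_EXPOSED = 10
_COL_ANCHOR_NOISE_FLAG = 11
_COL_ANCHOR_NOISE_PICK = 12
_COL_WASH_NOISE_FLAG = 13
_COL_WASH_NOISE_PICK = 14
_NBASE = 15
_PER_COMORB = 6  # presence, same-stay, direction, gap component, gap value, stay length
_PER_STAY = 4  # date, length, noise pool flag, noise pick


def _stay_len(u: np.ndarray, mean_days: float) -> np.ndarray:
    """Exponential-quantile stay length in days, capped for plausibility."""
    return np.minimum(np.floor(-mean_days * np.log1p(-u)), 60.0).astype(np.int64)


def generate_registry(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a synthetic registry as a tidy event table.

    Returns a DataFrame with columns ``patient_id, sex, birth_year, stay_id,
    admission_date, release_date, code`` — one row per diagnosis coded at a
    stay.  Identical (config, seed) yields an identical table.
    """
    n = config.n_patients
    codes_c = config.comorbidity_codes
    C = len(codes_c)
    K = config.max_extra_stays
    ncols = _NBASE + _PER_COMORB * C + _PER_STAY * K

    rng = np.random.default_rng(np.random.PCG64(np.random.SeedSequence(config.seed)))
    U = rng.random((n, ncols))

    obs_lo = _day(config.observation_start)
    obs_hi = _day(config.period_end)
    wash_lo = _day(config.period_start)
    wash_hi = obs_lo - 1
    has_washout_era = wash_hi >= wash_lo and config.washout_fraction > 0

    win_years = config.window_starts()
    W = len(win_years)
    win_lo = np.array([_day(dt.date(y, 1, 1)) for y in win_years])
    win_hi = np.array(
        [min(_day(dt.date(y + 1, 12, 31)), obs_hi) for y in win_years]
    )

    pid = np.arange(n, dtype=np.int64)
    female = U[:, _COL_SEX] < config.sex_ratio
    sidx = np.where(female, 0, 1)
    didx = np.minimum((U[:, _COL_DECADE] * len(DECADES)).astype(np.int64), len(DECADES) - 1)
    decade_lo = 10 + 10 * didx
    widx = np.minimum((U[:, _COL_WINDOW] * W).astype(np.int64), W - 1)

    # anchor admission, kept >= 1 day away from the observation-era bounds so
    # that a paired diagnosis can always be placed strictly before or after
    alo = np.maximum(win_lo[widx], obs_lo + 1)
    ahi = np.minimum(win_hi[widx], obs_hi - 1)
    anchor = alo + (U[:, _COL_ANCHOR] * (ahi - alo + 1)).astype(np.int64)

    adates = pd.to_datetime(anchor, unit="D")
    age = decade_lo + (U[:, _COL_AGE] * 10).astype(np.int64)
    # mid-year (July 1) birthday convention, mirrored by the cohort module
    birth_year = adates.year.to_numpy() - age - (adates.month.to_numpy() < 7)

    p_exp = config.prevalence_array(config.exposure_code)[didx, sidx]
    exposed = U[:, _COL_EXPOSED] < p_exp

    tf, tm = config.theta_by_sex()
    theta = np.where(female, tf, tm)
    p_first = config.rho / (1.0 + config.rho) if config.rho >= 0 else 0.5

    cumw = config.gap_mixture.cumulative_weights()
    gap_lo = np.array([r[0] for r in config.gap_mixture.ranges])
    gap_hi = np.array([r[1] for r in config.gap_mixture.ranges])

    noise_an = np.asarray(config.noise_codes, dtype=object)
    noise_oz = np.asarray(config.oz_codes, dtype=object)

    def noise_pick(u_flag: np.ndarray, u_pick: np.ndarray) -> np.ndarray:
        use_oz = u_flag < config.oz_fraction
        ian = np.minimum((u_pick * len(noise_an)).astype(np.int64), len(noise_an) - 1)
        ioz = np.minimum((u_pick * len(noise_oz)).astype(np.int64), len(noise_oz) - 1)
        return np.where(use_oz, noise_oz[ioz], noise_an[ian])

    def noise_pick_an(u_pick: np.ndarray) -> np.ndarray:
        # anchor and washout stays must survive the A-N chapter filter, or
        # stratum assignment / washout status would shift post-filter
        ian = np.minimum((u_pick * len(noise_an)).astype(np.int64), len(noise_an) - 1)
        return noise_an[ian]

    # event accumulators
    ev_pid: list[np.ndarray] = []
    ev_stay: list[np.ndarray] = []
    ev_adm: list[np.ndarray] = []
    ev_rel: list[np.ndarray] = []
    ev_code: list[np.ndarray] = []

    def emit(mask: np.ndarray, stay_id: np.ndarray, adm: np.ndarray,
             rel: np.ndarray, code: np.ndarray | str) -> None:
        if not mask.any():
            return
        ev_pid.append(pid[mask])
        ev_stay.append(stay_id[mask])
        ev_adm.append(adm[mask])
        ev_rel.append(np.minimum(rel[mask], obs_hi))
        if isinstance(code, str):
            ev_code.append(np.full(int(mask.sum()), code, dtype=object))
        else:
            ev_code.append(code[mask])

    anchor_stay = pid * 100
    anchor_len = _stay_len(U[:, _COL_ANCHOR_LEN], config.mean_stay_days)
    anchor_rel = anchor + anchor_len

    # per-comorbidity assignments
    present = np.zeros((C, n), dtype=bool)
    same_stay = np.zeros((C, n), dtype=bool)
    comorb_day = np.zeros((C, n), dtype=np.int64)
    comorb_len = np.zeros((C, n), dtype=np.int64)
    for c in range(C):
        b = _NBASE + _PER_COMORB * c
        p_base = config.prevalence_array(codes_c[c])[didx, sidx]
        p_eff = np.where(exposed, _inflate(p_base, theta), p_base)
        present[c] = U[:, b] < p_eff
        dual = present[c] & exposed
        same_stay[c] = dual & (U[:, b + 1] < config.p_same_stay)
        expo_first = U[:, b + 2] < p_first
        comp = np.minimum(np.searchsorted(cumw, U[:, b + 3], side="right"), len(cumw) - 1)
        gap = gap_lo[comp] + (U[:, b + 4] * (gap_hi[comp] - gap_lo[comp] + 1)).astype(np.int64)
        comorb_day[c] = np.where(
            expo_first,
            np.minimum(anchor + gap, obs_hi),
            np.maximum(anchor - gap, obs_lo),
        )
        comorb_len[c] = _stay_len(U[:, b + 5], config.mean_stay_days)

    any_unexp_comorb = (~exposed) & present.any(axis=0)

    # anchor-stay rows
    emit(exposed, anchor_stay, anchor, anchor_rel, config.exposure_code)
    for c in range(C):
        at_anchor = present[c] & (~exposed | same_stay[c])
        emit(at_anchor, anchor_stay, anchor, anchor_rel, codes_c[c])
    plain = (~exposed) & ~any_unexp_comorb
    anchor_noise = noise_pick_an(U[:, _COL_ANCHOR_NOISE_PICK])
    emit(plain, anchor_stay, anchor, anchor_rel, anchor_noise)

    # dedicated stays for exposed, time-separated comorbidities
    for c in range(C):
        ordered = present[c] & exposed & ~same_stay[c]
        stay_id = pid * 100 + 2 + K + c
        emit(ordered, stay_id, comorb_day[c], comorb_day[c] + comorb_len[c], codes_c[c])

    # washout-era stay (patients carrying one are excluded by the cohort step)
    if has_washout_era:
        wflag = U[:, _COL_WASH_FLAG] < config.washout_fraction
        wday = wash_lo + (U[:, _COL_WASH_DAY] * (wash_hi - wash_lo + 1)).astype(np.int64)
        wlen = _stay_len(U[:, _COL_WASH_LEN], config.mean_stay_days)
        wrel = np.minimum(wday + wlen, wash_hi)
        wstay = pid * 100 + 1
        wnoise = noise_pick_an(U[:, _COL_WASH_NOISE_PICK])
        if wflag.any():
            ev_pid.append(pid[wflag])
            ev_stay.append(wstay[wflag])
            ev_adm.append(wday[wflag])
            ev_rel.append(wrel[wflag])
            ev_code.append(wnoise[wflag])

    # extra stays with filler codes; for unexposed patients they never precede
    # the anchor (the anchor must remain the first admission)
    m_extra = np.minimum(
        stats.poisson.ppf(U[:, _COL_NSTAYS], config.mean_stays), K
    ).astype(np.int64)
    for k in range(K):
        b = _NBASE + _PER_COMORB * C + _PER_STAY * k
        active = m_extra > k
        start = np.where(exposed, obs_lo, anchor)
        day = start + (U[:, b] * (obs_hi - start + 1)).astype(np.int64)
        length = _stay_len(U[:, b + 1], config.mean_stay_days)
        stay_id = pid * 100 + 2 + k
        code = noise_pick(U[:, b + 2], U[:, b + 3])
        emit(active, stay_id, day, day + length, code)

    events = pd.DataFrame(
        {
            "patient_id": np.concatenate(ev_pid),
            "stay_id": np.concatenate(ev_stay),
            "admission_date": pd.to_datetime(np.concatenate(ev_adm), unit="D"),
            "release_date": pd.to_datetime(np.concatenate(ev_rel), unit="D"),
            "code": np.concatenate(ev_code),
        }
    )
    events["sex"] = np.where(female, "female", "male")[events["patient_id"].to_numpy()]
    events["birth_year"] = birth_year[events["patient_id"].to_numpy()]
    events = events.sort_values(
        ["patient_id", "admission_date", "stay_id", "code"], kind="mergesort"
    ).reset_index(drop=True)
    return events[
        ["patient_id", "sex", "birth_year", "stay_id", "admission_date", "release_date", "code"]
    ]


def _inflate(p: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Vectorized odds-scale inflation with per-patient theta."""
    odds = p / (1.0 - p)
    to = theta * odds
    return to / (1.0 + to)


def write_registry_csv(events: pd.DataFrame, path) -> None:
    """Write events in the canonical CSV schema with ISO-8601 dates."""
    out = events.copy()
    out["admission_date"] = out["admission_date"].dt.strftime("%Y-%m-%d")
    out["release_date"] = out["release_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_registry_csv(path) -> pd.DataFrame:
    """Read the canonical registry CSV, validating the schema."""
    from .errors import DataError

    df = pd.read_csv(path, dtype={"code": str})
    required = [
        "patient_id", "sex", "birth_year", "stay_id",
        "admission_date", "release_date", "code",
    ]
    for col in required:
        if col not in df.columns:
            raise DataError(f"registry CSV missing required column {col!r}")
    df["admission_date"] = pd.to_datetime(df["admission_date"])
    df["release_date"] = pd.to_datetime(df["release_date"])
    return df[required]
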