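"""End-to-end orchestration: simulate -> cohort -> screen -> TOR -> sex /
sensitivity -> report, with deterministic CSV outputs and a metadata sidecar.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import cohort as coh
from .association import screen_pairs
from .errors import ConfigError, DataError
from .sex_sensitivity import (
    DEFAULT_SENSITIVITY_CODES,
    sensitivity_exclude,
    sex_specific_or,
    sex_stratified_run,
)
from .synthetic_registry import (
    GeneratorConfig,
    generate_registry,
    read_registry_csv,
    write_registry_csv,
)
from .time_order import DEFAULT_GAP_EDGES, compute_tor, ordered_pairs

__all__ = ["Thresholds", "RunConfig", "run_full_analysis", "summarize_table1"]

_ANCHOR_POLICIES = ("first-exposure-else-first-admission",)
_FAMILY_POLICIES = ("per-decade-pooled",)
_TIE_POLICIES = ("exclude-ties",)


class Thresholds(BaseModel):
    model_config = ConfigDict(frozen=True)

    min_occurrence: int = Field(default=100, gt=0)
    or_threshold: float = Field(default=1.5, gt=0.0)
    alpha: float = Field(default=0.01, gt=0.0, lt=1.0)


class RunConfig(BaseModel):
    """Configuration of a full pipeline run.

    Either ``registry`` (path to a registry CSV) or ``generator`` (a
    :class:`GeneratorConfig` to simulate one) must be provided.  Policy
    strings come from closed vocabularies and are echoed into the metadata
    sidecar so every reported number is auditable.
    """

    model_config = ConfigDict(frozen=True)

    registry: Path | None = None
    out_dir: Path
    exposure_code: str = "E66"
    comorbidity_codes: tuple[str, ...] = ("F32",)
    thresholds: Thresholds = Thresholds()
    gap_edges: tuple[int, ...] = DEFAULT_GAP_EDGES
    anchor_policy: str = "first-exposure-else-first-admission"
    bonferroni_family: str = "per-decade-pooled"
    tie_policy: str = "exclude-ties"
    sensitivity_codes: tuple[str, ...] = tuple(sorted(DEFAULT_SENSITIVITY_CODES))
    table1_codes: tuple[str, ...] = ()
    seed: int = 0
    generator: GeneratorConfig | None = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.registry is None and self.generator is None:
            raise ConfigError("RunConfig needs either a registry path or a generator config")
        if self.anchor_policy not in _ANCHOR_POLICIES:
            raise ConfigError(f"unknown anchor_policy {self.anchor_policy!r}")
        if self.bonferroni_family not in _FAMILY_POLICIES:
            raise ConfigError(f"unknown bonferroni_family {self.bonferroni_family!r}")
        if self.tie_policy not in _TIE_POLICIES:
            raise ConfigError(f"unknown tie_policy {self.tie_policy!r}")
        if list(self.gap_edges) != sorted(set(self.gap_edges)) or (
            self.gap_edges and self.gap_edges[0] < 1
        ):
            raise ConfigError("gap_edges must be strictly ascending positive day counts")
        return self


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.10g")


def _prepare_cohort(events: pd.DataFrame, exposure_code: str):
    ev = coh.filter_chapters(events)
    ev = coh.apply_washout(ev)
    fo = coh.first_occurrences(ev)
    prof = coh.patient_profiles(ev)
    strata, excl = coh.assign_strata(fo, prof, exposure_code)
    return ev, fo, prof, strata, excl


def summarize_table1(
    events: pd.DataFrame,
    strata: pd.DataFrame,
    codes: Sequence[str] = (),
) -> pd.DataFrame:
    """Cohort characteristics per exposure status and sex.

    Subject counts, mean+-SD age at anchor, stays, hospital days (inclusive,
    release - admission + 1, summed per patient), distinct diagnoses per
    patient, and co-diagnosis percentages for ``codes``.  Empty cells emit a
    zero-count row with nulls elsewhere.
    """
    ev = events.merge(strata[["patient_id", "exposed", "age"]], on="patient_id")
    stays = ev.drop_duplicates(["patient_id", "stay_id"]).copy()
    stays["days"] = (stays["release_date"] - stays["admission_date"]).dt.days + 1
    per_patient = stays.groupby("patient_id").agg(
        n_stays=("stay_id", "size"), hospital_days=("days", "sum")
    )
    per_patient["n_diagnoses"] = ev.groupby("patient_id")["code"].nunique()
    info = strata.set_index("patient_id")[["exposed", "sex", "age"]].join(per_patient)

    rows = []
    for exposed in (True, False):
        for sex in ("all", "female", "male"):
            sub = info[info["exposed"] == exposed]
            if sex != "all":
                sub = sub[sub["sex"] == sex]
            row: dict = {"exposed": exposed, "sex": sex, "n_subjects": len(sub)}
            if len(sub) == 0:
                for k in ("age_mean", "age_sd", "stays_mean", "stays_sd",
                          "hospital_days_mean", "hospital_days_sd",
                          "diagnoses_mean", "diagnoses_sd"):
                    row[k] = np.nan
                for code in codes:
                    row[f"pct_{code}"] = np.nan
            else:
                row.update(
                    age_mean=sub["age"].mean(), age_sd=sub["age"].std(ddof=1),
                    stays_mean=sub["n_stays"].mean(), stays_sd=sub["n_stays"].std(ddof=1),
                    hospital_days_mean=sub["hospital_days"].mean(),
                    hospital_days_sd=sub["hospital_days"].std(ddof=1),
                    diagnoses_mean=sub["n_diagnoses"].mean(),
                    diagnoses_sd=sub["n_diagnoses"].std(ddof=1),
                )
                for code in codes:
                    carriers = set(ev.loc[ev["code"] == code, "patient_id"])
                    row[f"pct_{code}"] = 100.0 * sub.index.isin(carriers).mean()
            rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole pipeline and persist every report under ``out_dir``.

    Returns a dict with the output paths and the metadata mapping.  Every
    reported number is recomputable from the persisted intermediate CSVs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds

    if config.registry is not None:
        events = read_registry_csv(config.registry)
    else:
        gen = config.generator.model_copy(update={"seed": config.seed})
        events = generate_registry(gen)
        write_registry_csv(events, out / "registry.csv")

    n_patients_in = int(events["patient_id"].nunique())
    ev, fo, prof, strata, excl = _prepare_cohort(events, config.exposure_code)
    n_retained = int(strata["patient_id"].nunique())
    n_washed_out = n_patients_in - int(prof["patient_id"].nunique())

    _write_csv(fo, out / "first_occurrences.csv")
    _write_csv(strata, out / "strata.csv")
    _write_csv(excl, out / "exclusions.csv")

    assoc, meta_assoc = screen_pairs(
        fo, strata, config.exposure_code, config.comorbidity_codes,
        min_occurrence=thr.min_occurrence, or_threshold=thr.or_threshold,
        alpha=thr.alpha,
    )
    _write_csv(assoc, out / "associations.csv")

    tor_frames = []
    for code in config.comorbidity_codes:
        pairs = ordered_pairs(fo, config.exposure_code, code)
        for by_sex in (False, True):
            tor = compute_tor(pairs, edges=config.gap_edges,
                              profiles=prof, by_sex=by_sex)
            if not tor.empty:
                tor.insert(0, "code_b", code)
                tor.insert(0, "code_a", config.exposure_code)
                tor_frames.append(tor)
    tor_all = (
        pd.concat(tor_frames, ignore_index=True)
        if tor_frames
        else pd.DataFrame()
    )
    _write_csv(tor_all, out / "tor.csv")

    sex_frames = []
    for sex in ("female", "male"):
        if (strata["sex"] == sex).any():
            res, _ = sex_stratified_run(
                fo, strata, sex, config.exposure_code, config.comorbidity_codes,
                min_occurrence=thr.min_occurrence, or_threshold=thr.or_threshold,
                alpha=thr.alpha,
            )
            sex_frames.append(res)
    _write_csv(
        pd.concat(sex_frames, ignore_index=True) if sex_frames else pd.DataFrame(),
        out / "associations_by_sex.csv",
    )

    sexor_rows = []
    exposed_decades = sorted(strata.loc[strata["exposed"], "age_decade"].unique())
    for code in config.comorbidity_codes:
        for dec in exposed_decades:
            r = sex_specific_or(fo, strata, code, dec)
            sexor_rows.append(r.__dict__)
    _write_csv(pd.DataFrame(sexor_rows), out / "sex_specific_or.csv")

    ev_sens = sensitivity_exclude(ev, config.sensitivity_codes)
    fo_s = coh.first_occurrences(ev_sens)
    prof_s = coh.patient_profiles(ev_sens)
    strata_s, _ = coh.assign_strata(fo_s, prof_s, config.exposure_code)
    sens_codes = [c for c in config.comorbidity_codes if c not in config.sensitivity_codes]
    if sens_codes and not strata_s.empty:
        sens, _ = screen_pairs(
            fo_s, strata_s, config.exposure_code, sens_codes,
            min_occurrence=thr.min_occurrence, or_threshold=thr.or_threshold,
            alpha=thr.alpha,
        )
        sens = sens.copy()
        sens.insert(0, "analysis", "sensitivity")
    else:
        sens = pd.DataFrame()
    _write_csv(sens, out / "associations_sensitivity.csv")

    table1 = summarize_table1(ev, strata, config.table1_codes or config.comorbidity_codes)
    _write_csv(table1, out / "table1.csv")

    metadata = {
        "seed": config.seed,
        "exposure_code": config.exposure_code,
        "comorbidity_codes": list(config.comorbidity_codes),
        "thresholds": thr.model_dump(),
        "gap_edges": list(config.gap_edges),
        "policies": {
            "anchor": config.anchor_policy,
            "bonferroni_family": config.bonferroni_family,
            "ties": config.tie_policy,
            "age_convention": coh.AGE_CONVENTION,
        },
        "bonferroni_m": meta_assoc["m"],
        "counts": {
            "patients_in": n_patients_in,
            "washed_out": n_washed_out,
            "age_excluded": int(len(excl)),
            "retained": n_retained,
            "pairs_tested": int(
                ((~assoc["filtered"]) & (assoc["age_decade"] != "total")).sum()
            ),
            "pairs_filtered": int(assoc["filtered"].sum()),
            "patients_sensitivity": int(strata_s["patient_id"].nunique()),
        },
    }
    with open(out / "metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {"out_dir": out, "metadata": metadata, "associations": assoc, "tor": tor_all}
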