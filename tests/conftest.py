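"""Shared fixtures and helpers for the comorbscreen test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import comorbscreen as cs

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_config(**overrides) -> cs.GeneratorConfig:
    """Flat-prevalence generator config with overridable knobs."""
    base = dict(
        n_patients=5000,
        baseline_prevalence={"E66": 0.05, "F32": 0.04},
        theta=1.0,
        rho=1.0,
        seed=0,
    )
    base.update(overrides)
    return cs.GeneratorConfig(**base)


def run_cohort(events: pd.DataFrame, exposure_code: str = "E66"):
    """Registry events -> (events, first_occ, profiles, strata)."""
    ev = cs.apply_washout(cs.filter_chapters(events))
    fo = cs.first_occurrences(ev)
    prof = cs.patient_profiles(ev)
    strata, _ = cs.assign_strata(fo, prof, exposure_code)
    return ev, fo, prof, strata


def pair_arrays(strata, first_occ, code_a="E66", code_b="F32"):
    """Per-stratum (a, b, c, d) arrays for one pair over all strata."""
    tabs = cs.pair_tables(strata, first_occ, code_a, code_b)
    return (
        tabs["a"].to_numpy(float),
        tabs["b"].to_numpy(float),
        tabs["c"].to_numpy(float),
        tabs["d"].to_numpy(float),
    )


def simulate_pair_or(config: cs.GeneratorConfig):
    """Full generator -> cohort -> pooled-OR path for one pair."""
    ev = cs.generate_registry(config)
    _, fo, _, strata = run_cohort(ev, config.exposure_code)
    arrs = pair_arrays(strata, fo, config.exposure_code, config.comorbidity_codes[0])
    return arrs, cs.mantel_haenszel_or(arrs), cs.cmh_test(arrs), cs.crude_or(arrs)


@pytest.fixture(scope="session")
def demo_registry():
    """A mid-sized registry with an injected effect, shared across tests."""
    cfg = make_config(
        n_patients=30000,
        baseline_prevalence={"E66": 0.15, "F32": 0.10},
        theta=2.0,
        rho=1.5,
        seed=42,
    )
    events = cs.generate_registry(cfg)
    ev, fo, prof, strata = run_cohort(events)
    return {"config": cfg, "events": events, "ev": ev, "fo": fo,
            "prof": prof, "strata": strata}


def hand_events(rows) -> pd.DataFrame:
    """Build a small event table from (pid, sex, by, stay, adm, rel, code) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "sex", "birth_year", "stay_id",
                 "admission_date", "release_date", "code"],
    )
    df["admission_date"] = pd.to_datetime(df["admission_date"])
    df["release_date"] = pd.to_datetime(df["release_date"])
    return df
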