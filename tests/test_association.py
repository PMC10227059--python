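"""Mantel-Haenszel estimator, CMH test and the significance screen."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import comorbscreen as cs
from comorbscreen.association import (
    ContingencySeries,
    StratumTable,
    screen_associations,
)
from comorbscreen.errors import ConfigError, DataError

from conftest import make_config, pair_arrays, run_cohort, simulate_pair_or


def arrs(*tables):
    t = np.asarray(tables, dtype=float)
    return t[:, 0], t[:, 1], t[:, 2], t[:, 3]


class TestMantelHaenszel:
    def test_single_stratum_collapses_to_crude_or(self):
        mh = cs.mantel_haenszel_or(arrs((20, 10, 10, 20)))
        assert mh.or_mh == pytest.approx(4.0)
        assert mh.or_mh == cs.crude_or(arrs((20, 10, 10, 20)))

    def test_replicating_a_stratum_leaves_the_estimate_unchanged(self):
        one = cs.mantel_haenszel_or(arrs((20, 10, 10, 20)))
        two = cs.mantel_haenszel_or(arrs((20, 10, 10, 20), (20, 10, 10, 20)))
        assert two.or_mh == pytest.approx(one.or_mh)

    def test_rbg_interval_matches_direct_formula_transcription(self):
        # independent transcription of the Robins-Breslow-Greenland variance
        tables = [(10, 5, 4, 10), (6, 8, 2, 12)]
        a, b, c, d = arrs(*tables)
        n = a + b + c + d
        R_i, S_i = a * d / n, b * c / n
        P_i, Q_i = (a + d) / n, (b + c) / n
        R, S = R_i.sum(), S_i.sum()
        var = (
            (P_i * R_i).sum() / (2 * R**2)
            + (P_i * S_i + Q_i * R_i).sum() / (2 * R * S)
            + (Q_i * S_i).sum() / (2 * S**2)
        )
        z = stats.norm.ppf(0.975)
        expect_or = R / S
        lo = np.exp(np.log(expect_or) - z * np.sqrt(var))
        hi = np.exp(np.log(expect_or) + z * np.sqrt(var))
        mh = cs.mantel_haenszel_or(arrs(*tables))
        assert mh.or_mh == pytest.approx(expect_or, rel=1e-12)
        assert mh.ci_low == pytest.approx(lo, rel=1e-12)
        assert mh.ci_high == pytest.approx(hi, rel=1e-12)

    def test_zero_denominator_returns_sentinel_not_crash(self):
        mh = cs.mantel_haenszel_or(arrs((5, 3, 0, 7)))
        assert np.isinf(mh.or_mh) and not mh.defined
        mh = cs.mantel_haenszel_or(arrs((0, 3, 5, 7)))
        assert mh.or_mh == 0.0 and not mh.defined
        mh = cs.mantel_haenszel_or(arrs((0, 3, 0, 7)))
        assert np.isnan(mh.or_mh) and not mh.defined

    @given(seed=st.integers(0, 10**6))
    def test_stratum_order_is_irrelevant(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 30, size=(4, 4))
        mh1 = cs.mantel_haenszel_or(arrs(*t))
        perm = rng.permutation(4)
        mh2 = cs.mantel_haenszel_or(arrs(*t[perm]))
        assert mh1.or_mh == pytest.approx(mh2.or_mh, rel=1e-12)
        assert mh1.ci_low == pytest.approx(mh2.ci_low, rel=1e-12)

    def test_accepts_contingency_series_container(self):
        series = ContingencySeries(
            "E66", "F32", 40,
            [StratumTable(2003, 20, 10, 10, 20), StratumTable(2005, 6, 8, 2, 12)],
        )
        mh = cs.mantel_haenszel_or(series)
        assert mh.or_mh == cs.mantel_haenszel_or(arrs((20, 10, 10, 20), (6, 8, 2, 12))).or_mh


class TestCmhTest:
    def test_perfect_balance_gives_zero_statistic(self):
        res = cs.cmh_test(arrs((10, 10, 10, 10)))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    @given(seed=st.integers(0, 10**6))
    def test_single_stratum_equals_scaled_pearson_chi_square(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 40, size=4)
        n = t.sum()
        pearson = stats.chi2_contingency(t.reshape(2, 2), correction=False).statistic
        res = cs.cmh_test(arrs(tuple(t)))
        assert res.statistic == pytest.approx(pearson * (n - 1) / n, rel=1e-10)

    def test_degenerate_strata_contribute_nothing(self):
        informative = arrs((12, 5, 6, 9))
        with_junk = arrs((12, 5, 6, 9), (0, 0, 0, 0), (1, 0, 0, 0))
        assert cs.cmh_test(with_junk).statistic == pytest.approx(
            cs.cmh_test(informative).statistic
        )
        assert cs.cmh_test(with_junk).n_strata_used == 1

    def test_all_degenerate_gives_p_one_with_flag(self):
        res = cs.cmh_test(arrs((0, 0, 0, 0), (3, 0, 0, 0)))
        assert res.p_value == 1.0 and res.degenerate


class TestConfoundingAdjustment:
    def test_crude_biased_but_mh_unbiased_under_null_confounding(self):
        cfg = cs.confounded_scenario(make_config(n_patients=100000, theta=1.0, seed=21))
        arrs_, mh, _, crude = simulate_pair_or(cfg)
        assert crude > 1.1
        assert 0.95 <= mh.or_mh <= 1.05

    def test_theta_recovered_inside_ci_with_confounded_ages(self):
        cfg = cs.confounded_scenario(make_config(n_patients=100000, theta=2.5, seed=22))
        _, mh, _, _ = simulate_pair_or(cfg)
        assert mh.ci_low <= 2.5 <= mh.ci_high


class TestContingencyConstruction:
    def test_enumerated_four_patient_window(self, demo_registry=None):
        strata = pd.DataFrame(
            {
                "patient_id": [1, 2, 3, 4],
                "sex": ["female"] * 4,
                "exposed": [True, True, False, False],
                "anchor_date": pd.to_datetime(["2005-01-01"] * 4),
                "age": [45] * 4,
                "age_decade": [40] * 4,
                "window": [2005] * 4,
            }
        )
        fo = pd.DataFrame(
            {
                "patient_id": [1, 1, 2, 3],
                "code": ["E66", "F32", "E66", "F32"],
                "first_date": pd.to_datetime(["2005-01-01"] * 4),
                "first_stay_id": [1, 1, 2, 3],
            }
        )
        series = cs.build_contingency_series(strata, fo, "E66", "F32", 40)
        assert len(series.tables) == 1
        t = series.tables[0]
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_identical_codes_rejected(self):
        with pytest.raises(ConfigError):
            cs.pair_tables(pd.DataFrame(), pd.DataFrame(), "E66", "E66")

    def test_matches_brute_force_double_loop(self):
        cfg = make_config(
            n_patients=3000, baseline_prevalence={"E66": 0.3, "F32": 0.25},
            theta=2.0, seed=17,
        )
        ev = cs.generate_registry(cfg)
        _, fo, _, strata = run_cohort(ev)
        tabs = cs.pair_tables(strata, fo, "E66", "F32")
        has_a = set(fo.loc[fo["code"] == "E66", "patient_id"])
        has_b = set(fo.loc[fo["code"] == "F32", "patient_id"])
        for (dec, win), row in tabs.iterrows():
            cell = {"a": 0, "b": 0, "c": 0, "d": 0}
            sub = strata[(strata["age_decade"] == dec) & (strata["window"] == win)]
            for pid in sub["patient_id"]:
                ina, inb = pid in has_a, pid in has_b
                cell["a" if ina and inb else "b" if ina else "c" if inb else "d"] += 1
            assert (row.a, row.b, row.c, row.d) == (
                cell["a"], cell["b"], cell["c"], cell["d"]
            )

    def test_patients_never_leak_across_windows(self, demo_registry):
        strata, fo = demo_registry["strata"], demo_registry["fo"]
        tabs = cs.pair_tables(strata, fo, "E66", "F32")
        assert tabs[["a", "b", "c", "d"]].to_numpy().sum() == len(strata)


class TestScreen:
    def _draft(self, **kw):
        base = dict(code_a="E66", code_b="F32", age_decade=40,
                    or_mh=2.0, p_raw=0.001, n_cooccur=500)
        base.update(kw)
        return base

    def test_occurrence_filter_excludes_from_family_and_report(self):
        drafts = pd.DataFrame([
            self._draft(n_cooccur=99, code_b="F20"),
            self._draft(n_cooccur=100, code_b="F32"),
            self._draft(n_cooccur=500, code_b="F41"),
        ])
        out, meta = screen_associations(drafts)
        assert meta["m"] == 2
        assert out.loc[out["code_b"] == "F20", "filtered"].item()
        assert not out.loc[out["code_b"] == "F20", "significant"].item()
        assert out.loc[out["code_b"] == "F32", "significant"].item()

    def test_bonferroni_pushes_borderline_p_over_alpha(self):
        drafts = pd.DataFrame([self._draft(p_raw=0.004)] * 3).assign(
            code_b=["F32", "F33", "F41"]
        )
        out, _ = screen_associations(drafts)
        assert np.allclose(out["p_corr"], 0.012)
        assert not out["significant"].any()

    def test_small_or_blocks_significance_despite_tiny_p(self):
        drafts = pd.DataFrame(
            [self._draft(p_raw=1e-6, or_mh=1.4)]
            + [self._draft(code_b=f"F{i:02d}") for i in range(40, 40 + 9)]
        )
        out, meta = screen_associations(drafts, m=1000)
        row = out.iloc[0]
        assert row["p_corr"] == pytest.approx(1e-3)
        assert not row["significant"]

    def test_p_corr_monotone_bounded_and_capped(self):
        drafts = pd.DataFrame(
            [self._draft(p_raw=p, code_b=f"F{i:02d}")
             for i, p in enumerate([1e-7, 1e-4, 0.02, 0.9])]
        )
        out, meta = screen_associations(drafts)
        pc = out.sort_values("p_raw")["p_corr"].to_numpy()
        assert (np.diff(pc) >= 0).all()
        assert (out["p_corr"] >= out["p_raw"]).all()
        assert pc.max() <= 1.0

    def test_empty_family_rejected(self):
        drafts = pd.DataFrame([self._draft(n_cooccur=10)])
        with pytest.raises(DataError):
            screen_associations(drafts)
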