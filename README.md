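# comorbscreen

Registry-wide comorbidity screening for longitudinal inpatient data:
stratified Cochran–Mantel–Haenszel (CMH) association tests of diagnosis
pairs against an index diagnosis, plus a time-order-ratio analysis of which
diagnosis tends to come first.

## The problem

National hospital registries record, per stay, the level-3 ICD-10 diagnoses
a patient received (e.g. E66 obesity, F32 depressive episode). Given such a
table — one row per (patient, stay, diagnosis) — an epidemiologist wants to
know, for an index diagnosis like obesity:

1. **Association** — which diagnoses co-occur with the index diagnosis more
   often than expected, after adjusting for age and calendar period?
2. **Direction** — among patients who receive both diagnoses, which one
   tends to be recorded first, and at what time lag?

Real registries of this kind are access-restricted, so the package ships a
first-class synthetic registry generator with *known* injected effects: an
odds multiplier θ for each comorbidity given the index diagnosis (held
common across strata, so the CMH common-odds-ratio assumption holds by
construction) and a direction bias ρ (the index diagnosis comes first with
probability ρ/(1+ρ) among time-separated dual diagnoses). Every statistical
claim the pipeline makes can therefore be checked against ground truth.

## The method

**Cohort.** Codes outside ICD-10 chapters A–N are dropped. Patients with
any admission during the washout era (1997–2002) are removed whole, which
equalizes baseline health status; analysis covers 2003–2014. Each patient
is anchored once — at the first index diagnosis if exposed, else at the
first admission — and assigned to one (age decade 10–19 … 70–79,
2-year calendar window) stratum, so strata partition the cohort.

**Association.** For each pair and stratum a 2×2 table
(a = exposed-with-comorbidity, b = exposed-without, c, d likewise
unexposed) is built and pooled with the Mantel–Haenszel common odds ratio

    OR_MH = Σᵢ(aᵢdᵢ/nᵢ) / Σᵢ(bᵢcᵢ/nᵢ)

with a 95% CI from the Robins–Breslow–Greenland variance of log OR_MH, and
the CMH chi-square statistic (1 df, no continuity correction) for the
p-value. Pairs with fewer than 100 co-occurrences are filtered as quality
control; the rest are Bonferroni-corrected, and a pair is *significant*
when OR_MH > 1.5 and corrected p < 0.01.

**Time order.** For dual-diagnosed patients the gap between first
occurrences is classed as same-stay, ≤360 days, 361–1080 days, or >1080
days (a 360-day year). Per class the time-order ratio
TOR(A→B) = N(A first)/N(B first) is reported with an exact two-sided
binomial sign test of N(A first) = N(B first); same-stay ties are counted
but excluded from the ratio and the test.

Sex-stratified screens, female-vs-male odds ratios within the exposed
cohort, and a sensitivity re-run excluding carriers of configurable somatic
codes (default E11, I10, I25) complete the pipeline.

## Worked example

```python
import comorbscreen as cs

cfg = cs.confounded_scenario(          # age-confounded prevalences
    cs.GeneratorConfig(
        n_patients=100_000,
        baseline_prevalence={"E66": 0.05, "F32": 0.04},
        theta=2.5,                     # injected common odds ratio
        rho=2.0,                       # injected direction bias
        seed=22,
    )
)
events = cs.generate_registry(cfg)
ev = cs.apply_washout(cs.filter_chapters(events))
fo = cs.first_occurrences(ev)
strata, _ = cs.assign_strata(fo, cs.patient_profiles(ev))

tabs = cs.pair_tables(strata, fo, "E66", "F32")
arrs = tuple(tabs[c].to_numpy(float) for c in "abcd")
mh = cs.mantel_haenszel_or(arrs)
print(f"crude OR     {cs.crude_or(arrs):.3f}")
print(f"MH pooled OR {mh.or_mh:.3f}  (95% CI {mh.ci_low:.3f}-{mh.ci_high:.3f})")
```

prints

```
crude OR     3.572
MH pooled OR 2.585  (95% CI 2.486-2.687)
```

The crude OR (3.57) is inflated because both the index diagnosis and the
comorbidity become more prevalent with age; the stratified MH estimate
recovers the injected θ = 2.5 inside its confidence interval. Continuing
with the time-order analysis:

```python
tor = cs.compute_tor(cs.ordered_pairs(fo, "E66", "F32"))
print(tor[["gap_class", "n_a_first", "n_b_first", "tor", "p_binomial"]])
```

```
gap_class  n_a_first  n_b_first       tor    p_binomial
same_stay          0          0       NaN           NaN
    lt_1y       1780        870  2.045977  3.562398e-71
 1y_to_3y       1162        596  1.949664  4.276609e-42
    gt_3y        690        311  2.218650  1.105899e-33
      all       3632       1777  2.043894 4.668421e-143
```

TOR ≈ 2 in every gap class — twice as many patients received the index
diagnosis first — recovering the injected ρ = 2.

A YAML-driven CLI wraps the same pipeline
(`comorbscreen simulate|cohort|screen|tor|sexstrat|sensitivity|report|all`),
writing association, TOR, sex and sensitivity CSVs plus a `metadata.json`
sidecar with seeds, thresholds, policy strings and filter counts.

## Documentation

See `docs/methods.md` for the model, its assumptions, all tunable
parameters, numerical conventions and known limitations.
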