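# Methods

## Scope and data model

The pipeline analyses a longitudinal inpatient registry: one row per
(patient, hospital stay, level-3 ICD-10 diagnosis) with sex, birth year and
admission/release dates. Everything downstream of the raw table is
deterministic given the input and the configuration; everything upstream
(the synthetic registry) is deterministic given a config and a seed.

## Cohort construction

* **Chapter filter.** Only codes matching `[A-Z][0-9]{2}` are accepted;
  malformed strings are an error naming the row. Chapters O–Z (pregnancy,
  perinatal, congenital, findings, external causes, health-contact factors)
  are excluded from analysis.
* **Washout.** Any patient with an admission during 1997–2002 is removed
  entirely (all-or-nothing); remaining events are restricted to 2003–2014.
  This yields a cohort with five hospitalization-free years at baseline and
  sidesteps the coding-system change of the early 2000s.
* **First occurrences.** Per (patient, code), the earliest admission
  carrying the code; same-date ties break toward the smallest stay id. The
  operation is idempotent.
* **Anchoring (design decision).** A patient who ages across decades during
  the observation period could in principle appear in several age groups.
  We anchor each patient exactly once — at the first index-diagnosis date
  if exposed, else at the first admission — so the (age decade × 2-year
  window) cells are disjoint, which the CMH pooling requires. The policy
  string is emitted in run metadata; alternative policies are an explicit
  extension point.
* **Age convention.** The registry carries birth year only. Age is
  completed years under a fixed July-1 birthday: age = year − birth_year −
  1 if the anchor falls before July, else year − birth_year. The synthetic
  generator inverts the same convention, so injected decades are recovered
  exactly.
* **Comorbidity presence** for the association tables is any occurrence
  during 2003–2014, not just inside the anchor window: the screen targets
  in-window co-diagnosis, while the window stratification serves
  confounding adjustment, not exposure timing.

## Association screen

Within each stratum the 2×2 table is (a, b, c, d) = (exposed-with,
exposed-without, unexposed-with, unexposed-without). Pooling uses:

* **Mantel–Haenszel OR**: `Σ(a_i d_i/n_i) / Σ(b_i c_i/n_i)`.
* **Robins–Breslow–Greenland variance** of log OR_MH for the 95% CI
  (normal quantiles). This variance is valid under both sparse-strata and
  large-strata asymptotics, which matters because young-decade strata can
  be thin.
* **CMH statistic** `(Σa_i − ΣE_i)² / ΣV_i` with hypergeometric mean
  `E_i = (a_i+b_i)(a_i+c_i)/n_i` and variance
  `V_i = (a_i+b_i)(c_i+d_i)(a_i+c_i)(b_i+d_i)/(n_i²(n_i−1))`, 1 df, no
  continuity correction, two-sided by its chi-square form. Strata with
  n ≤ 1 or a zero margin carry no information and are dropped; if all drop
  out the result is p = 1 with a degenerate flag.
* **Zero cells** are handled by sentinels (OR = ∞ when the pooled
  denominator is 0, OR = 0 when the numerator is 0, NaN when both), never
  by 0.5-padding — padding silently changes estimates, a sentinel forces
  explicit handling. The significance conjunction is applied literally to
  the sentinel value.
* **Screening rule.** Pairs with fewer than 100 co-occurrences (Σa over
  the group) are filtered as quality control and excluded from the
  Bonferroni family m; survivors get `p_corr = min(1, m·p_raw)` and are
  significant iff OR_MH > 1.5 and p_corr < 0.01. m counts the per-decade
  tests of one run (a single pooled family — the most conservative
  defensible choice); the pooled "total" summary rows are corrected with
  the same m but do not enter it. m and all thresholds are emitted in run
  metadata. Risk ratios are not computed; the odds ratio is the effect
  measure throughout.

## Time-order analysis

For each dual-diagnosed patient the gap between first occurrences is
classed as same-stay, ≤360, 361–1080 or >1080 days. The 360-day year and
the ≤-boundary convention ("exactly 360 days" counts as within a year) are
deliberate choices; class edges are a user-settable ascending day list, so
a five-year split (or any other) is available via configuration. The
time-order ratio TOR(A→B) = N(A first)/N(B first) is accompanied by an
exact two-sided binomial sign test, p = min(1, 2·min(P(X≤k), P(X≥k))) with
X ~ Binomial(N(A first)+N(B first), ½). Same-stay ties (and same-day ties
across stays) are reported but excluded from the ratio and the test: a
ratio of directed counts cannot absorb ties. TOR p-values are reported raw
(with 0.05/0.01/0.001 star levels in mind); multiplicity correction across
pairs and classes is left to the user.

## Sex and sensitivity analyses

Sex-stratified screens rerun the identical pipeline on one sex. The
female-vs-male OR within the exposed cohort uses the same MH machinery,
pooled over 2-year windows within an age decade, female odds in the
numerator. The sensitivity analysis removes — patient-level, idempotent —
everyone ever carrying one of the configured somatic codes (default E11
diabetes, I10 hypertension, I25 coronary artery disease) within the
observation window (the washout design leaves no earlier lookback) and
reruns the screen with results tagged `sensitivity`.

## The synthetic registry

The generator emulates the structural features the pipeline depends on;
it is not a calibrated model of any real population.

* Each patient draws sex (P(female) = `sex_ratio`), an age decade
  (uniform over 10–79, so every analysis decade is populated), a 2-year
  window, and an anchor admission inside it. Additional stays are Poisson
  (`mean_stays`, capped at `max_extra_stays`) with exponential-quantile
  lengths (`mean_stay_days`, capped at 60 days). A `washout_fraction`
  share receives one 1997–2002 stay and is thereby excluded downstream.
* **θ (odds multiplier).** Exposure is Bernoulli with the configured
  (decade, sex) prevalence; each comorbidity is Bernoulli with baseline
  prevalence for unexposed patients and odds-inflated probability
  θ·odds/(1+θ·odds) for exposed ones. With sex-flat prevalences the
  per-stratum odds ratio equals θ exactly in expectation, making parameter
  recovery a sharp test. θ may differ by sex. A baseline probability of 1
  makes the inflation impossible and rejects the config naming the
  stratum.
* **ρ (direction bias).** Among exposed patients with a comorbidity, a
  `p_same_stay` share is co-coded at the anchor stay (a tie); the rest get
  a dedicated stay at anchor ± gap, exposure-first with probability
  ρ/(1+ρ). Gaps come from `gap_mixture`, a weighted mixture of uniform day
  ranges; the defaults (weights 0.45/0.30/0.25 over 1–360, 361–1080,
  1081–2400 days) were chosen once to populate all gap classes — no
  empirical gap distribution is being imitated. Dates are clipped to the
  observation era with at least one day kept on the intended side of the
  anchor, so clipping truncates gaps but never flips direction: TOR equals
  ρ in every class by construction.
* **Filler codes.** Extra stays carry filler diagnoses, a configurable
  fraction (default 10%) from O–Z chapters to exercise the chapter filter.
  Anchor and washout stays draw fillers from the A–N pool only, because a
  vanishing anchor stay would silently shift stratum assignment after
  filtering and a vanishing washout stay would un-wash the patient.
* **Determinism.** All randomness is consumed from a single PCG64 stream
  in a fixed per-patient column layout (row-major): identical (config,
  seed) is byte-identical, and enlarging `n_patients` reproduces the
  original patients exactly (the prefix-stability equivalent of
  per-patient substreams, but vectorizable).
* `confounded_scenario` replaces the prevalence maps with linear age
  gradients (0.05 → 0.35 across decades) for exposure and comorbidities
  while leaving θ untouched: the crude OR is biased upward, the stratified
  MH OR is not — the canonical demonstration of why the screen stratifies.

**What the generator does not emulate:** real ICD coding practice
(co-diagnosis correlations beyond the injected pair, coding drift,
under-diagnosis), mortality and censoring, outpatient care, seasonal
admission patterns, or realistic national prevalences. Passing tests
therefore certify the statistical machinery — estimator correctness,
confounding adjustment, calibration, directionality recovery — not the
epidemiology of any real registry.

## Verification problem sizes

The statistical guarantees are exercised at sizes chosen to make each
check sharp while staying cheap to rerun:

* θ-recovery and crude-vs-MH confounding: one run at n = 100,000.
* RBG CI coverage: 300 replicates at n = 5,000 (coverage SE ≈ 1.3%,
  against a 93–97% band).
* CMH type-I error: 2,000 replicates at n = 4,000 under the confounded
  null. The replicate size was set by the standard expected-cell-count
  rule: at n = 4,000 the thinnest confounded strata reach expected a-cells
  of about 5, inside the chi-square approximation's regime (smaller
  replicates make the asymptotic test visibly conservative, which would
  test the approximation's reach rather than the implementation).
* TOR recovery: one run with ~3,600 ordered pairs; sign-test size: 2,000
  replicates of ~100 ordered pairs (the exact test's attainable size is
  below nominal, so the check is one-sided against the binomial bound).

## Known limitations

* Single-anchor stratification is one defensible reading of an
  under-specified design; a multi-anchor (per-window re-assignment)
  policy would need a different pooling argument.
* The Bonferroni family is per-run; screening many comorbidity lists in
  separate runs multiplies families.
* The MH estimator assumes a common OR across strata; the generator makes
  that true by construction, real data need not.
* The CMH p-value is asymptotic; with very sparse strata (expected cells
  well below 5) it runs conservative.
* Percentages in the cohort summary use inclusive hospital days
  (release − admission + 1); conventions differ across registries.
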