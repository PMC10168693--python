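# Methods

## Model and procedure

The package treats a *comparison* as the unit of analysis: one
multilaboratory study (a pre-registered protocol run at ≥2 independent
sites) matched to at most 10 single-laboratory studies of the same
intervention, disease model and outcome. All effects are standardized mean
differences so outcomes measured on different scales are commensurable.

Per study, Cohen's d is the arm mean difference over the pooled SD, with
variance (n_t+n_c)/(n_t·n_c) + d²/(2(n_t+n_c)). Hedges' g = J·d,
J = 1 − 3/(4·df − 1), is the default metric because single-lab animal
studies are small (median ≈19 animals) and d is biased upward at small df;
Cohen's d remains available (`metric="d"`). Standard errors reported as SE
are converted to SD as SE·√n — the only conversion possible from extracted
summaries. Outcomes where lower values indicate benefit are sign-flipped
("oriented") before any pooling so a positive effect always favours
treatment.

Within a comparison the single-lab estimates are pooled with
DerSimonian–Laird random-effects inverse-variance weighting; the
multilaboratory study passes through the same code path as a k=1 pool
(τ²=0). Confidence intervals are plain z intervals (±1.96·se) without the
Knapp–Hartung adjustment, matching standard inverse-variance meta-analysis
practice for this kind of data.

Design contrasts:

* DSMD_i = d_single,i − d_multi,i, se² = se_s² + se_m² (the two designs'
  estimates are independent samples). Per-comparison DSMDs are combined by
  random-effects inverse-variance pooling by default. Whether such a
  combined estimate should weight comparisons by precision or equally is a
  genuinely open choice; an equal-weight mean (se = √(Σv_i)/k) and a
  fixed-effect variant are provided behind flags.
* ESR_i = ES_single,i / ES_multi,i on the oriented scale, summarised by
  median and range. A multilaboratory effect within 1e−8 of zero makes the
  ratio meaningless; such comparisons are flagged degenerate, logged, and
  excluded from the median.
* Direction counts use the strict inequality DSMD > 0; exact ties are
  reported separately rather than folded into either side.
* "CI falls outside" is implemented as *disjoint intervals* (the multilab
  interval entirely outside the single-lab pooled interval). This is the
  only reading that is well defined when one interval nests inside the
  other; each comparison's intervals are logged so the adjudication is
  auditable.

Quality: five binary practices are summed to a 0–5 score; distributions are
compared with a two-sided Mann–Whitney U test — exact enumeration when
n₁·n₂ ≤ 400 and there are no ties, otherwise the tie-corrected normal
approximation with continuity correction (scipy). Per-practice adherence is
reported descriptively only, with no per-item tests. Study matching scores
candidates by a weighted sum of per-feature similarities (binary for
species/sex, 1/(1+|Δ|) for timing, dose, measurement time and year; missing
features contribute 0) with seeded uniform tie-breaking at the selection
boundary, so selections are reproducible and auditable.

## Synthetic-data generator

The generator emulates the structure above on the standardized (unit
within-group SD) scale, so native measurement units play no role. Per
comparison: a true effect δ_i ~ N(μ_δ, τ_c²); a multilaboratory study with
C ∈ [2,5] centers, center shifts ~ N(0, τ_center²), and per-arm, per-center
samples of 8–24 (median total ≈115 animals, matching a median ≈111 in
published multicenter animal studies); 4–10 single-lab studies estimating
δ_i + b + u_j with u_j ~ N(0, τ_single²) and 5–14 per arm (median total
≈20, matching ≈19). Defaults: μ_δ = 0.5 and τ's of 0.2–0.3, typical
mid-size preclinical effects with moderate heterogeneity; the design bias
default b = 0.7 SMD mirrors the design difference reported in the
meta-epidemiological literature this package operationalises. Quality flags
are Bernoulli draws with per-design practice probabilities
({.94,.19,.69,.75,.38} multilab, {.57,.07,.24,.53,.38} single by default).
Optional significance gating redraws a single-lab study until its Welch
t-test is significant (two-sided by default, one-sided available), up to
`max_redraws` (logged); this models publication selection, the mechanism
usually invoked for small-study effects.

What the generator does **not** emulate: non-normal outcomes, unequal arm
sizes, correlated outcomes within studies, digitization error from
figure-extracted data, time trends, or any dependence of quality flags on
effect size. Passing recovery tests therefore shows the estimators and
pipeline are correct under the assumed model, not that real extraction
sheets satisfy those assumptions.

Reproducibility: each comparison uses an independent substream seeded by
(seed, comparison index), so corpora are bit-reproducible and extensible —
drawing more comparisons never changes earlier ones. Replicates in the
recovery experiment derive their seeds as seed + 100003·(r+1).

## Numerical choices and degenerate inputs

* Pooling requires strictly positive variances; k=1 pools return the input
  estimate. τ² is truncated at zero, and C ≤ 0 (identical weights to
  machine precision) yields τ² = 0.
* A zero pooled SD with unequal means raises (undefined SMD); with equal
  means the effect is 0 with an error-flagged zero variance.
* NR (not-reported) sample sizes are excluded from medians, ranges and
  totals and logged; a study using several species contributes one
  sample-size entry per species cohort; a center serving both experimental
  and coordinating roles is counted once in total-center descriptives.
  Medians use the midpoint convention for even counts.
* Problem sizes in the validation experiments: oracle-equivalence checks
  run 1,000 random instances at 1e−12; bias recovery uses one
  200-comparison corpus (Monte-Carlo SE ≈ 0.022); coverage uses 300
  replicates of the default 14-comparison corpus, sized so the binomial
  3σ band around 95% is ±3.8 points.

## Known limitations

* Inverse-variance pooling of SMDs has a small negative bias when n is
  small, because var(d) contains d²/(2N): larger observed effects receive
  systematically smaller weights. At the default single-lab sizes this
  shrinks the pooled DSMD by roughly 0.05 SMD below an injected bias of
  0.7 (visible only at high replication); it is a property of the
  estimator itself, shared by standard meta-analysis software, not of the
  implementation.
* The Mann–Whitney p-value under ties uses the normal approximation, which
  for very small tied samples can differ noticeably from the exact
  permutation null (U itself is always the exact midrank statistic).
* DSMD standard errors treat the two designs' pools as independent, which
  ignores any shared-outcome correlation induced by matching.
* The similarity score is a heuristic: the field describes matching
  criteria but no functional form, so the weighted sum with logged
  per-feature contributions was chosen for auditability; hierarchical
  matching can be mimicked with large weight ratios.
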