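# metacontrast

Meta-epidemiological comparison of effect sizes between **multilaboratory**
preclinical studies (one protocol run at two or more independent sites) and
conventional **single-laboratory** studies of the same intervention and
disease model. The package is aimed at meta-researchers and systematic
reviewers of animal studies who have extracted arm-level summary statistics
(mean, SD or SE, n per arm) and want to quantify how study design relates to
the size of the estimated treatment effect.

## What it computes

For each two-arm study, the standardized mean difference

    d = (m_t - m_c) / s_pooled,    s_pooled² = ((n_t-1)s_t² + (n_c-1)s_c²) / (n_t+n_c-2)
    var(d) = (n_t+n_c)/(n_t·n_c) + d²/(2(n_t+n_c))

with Hedges' small-sample correction g = J·d, J = 1 − 3/(4(n_t+n_c−2) − 1)
as the default metric. Effects are oriented so that positive values favour
treatment regardless of outcome polarity.

Within each *comparison* — one multilaboratory study matched to up to 10
single-lab studies on a shared outcome — the single-lab estimates are pooled
with a DerSimonian–Laird random-effects inverse-variance model
(τ² = max(0, (Q − (k−1))/C)). Two design contrasts follow:

* **DSMD** (difference in standardized mean differences):
  `DSMD_i = d(single-lab pool)_i − d(multilab)_i`, with
  `se² = se_s² + se_m²`; values above 0 mean the single-lab studies showed
  the larger effect. Per-comparison DSMDs are combined across comparisons by
  random-effects pooling.
* **ESR** (effect size ratio): `ESR_i = ES(single)_i / ES(multilab)_i`,
  summarised by its median and range; 1 means no difference.

The package also scores each study 0–5 on five bias-reducing practices
(randomization, low-risk randomization method, personnel blinding,
outcome-assessor blinding, complete outcome data) and compares the score
distributions between designs with a two-sided Mann–Whitney U test; ranks
candidate single-lab studies by similarity to a reference multilaboratory
study with seeded tie-breaking; and generates ground-truth synthetic corpora
(with configurable design bias, heterogeneity and significance-gated
publication selection) for validating every stage.

## Worked example

Simulate a corpus with the default study structure (14 comparisons,
multilaboratory studies with 2–5 centers and ≈110 animals, up to 10 small
single-lab studies per comparison, an injected single-lab inflation of
0.7 SMD), then run the full pipeline:

```sh
metacontrast simulate --seed 42 --out demo/sim
metacontrast compute --studies demo/sim/studies.csv \
    --characteristics src/metacontrast/data/multilab_characteristics.csv \
    --out demo/results
```

which prints

```
wrote 113 studies in 14 comparisons to demo/sim
pooled DSMD 0.54 [95% CI 0.39, 0.70] over 14 comparisons
median ESR 2.11 (range -4.80-5.46)
quality medians 2 (multilab) vs 2 (single), p=0.015
```

The pooled DSMD estimates the injected design bias (0.7; a 14-comparison
corpus is noisy — at 200 comparisons the estimate is 0.67 ± 0.02), the
median ESR above 1 says single-lab effects are typically about twice the
multilaboratory effect in this draw, and the Mann–Whitney p-value reflects
the different practice-adherence probabilities the generator assigns per
design. `demo/results/` then holds `report.json` (all statistics plus a
seed/config-hash manifest), `contrast.csv` (per-comparison DSMD/ESR) and two
forest plots (per-comparison panels and the pooled-DSMD diamond).

The same `compute` command runs on real extraction sheets: one CSV row per
study (or per center of a multilaboratory study, via the `center` column)
with `mean/dispersion/n` for both arms, `dispersion_kind` (SD or SE),
`direction`, `comparison_id` and the five quality flags.

Descriptives of the 16 published multilaboratory studies ship with the
package:

```sh
metacontrast report --characteristics src/metacontrast/data/multilab_characteristics.csv
```

returns median sample size 111 (range 23–384), 2145 animals in total, 91%
rodents, and a median of 4 total (3 experimental) centers per study.

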