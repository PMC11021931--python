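# sticklediv

Divergence statistics for fossil and extant stickleback trait series.

## The problem

A finely resolved Miocene lake deposit preserves a lineage of the fossil
stickleback *Gasterosteus doryssus* sampled at 18 roughly 1000-year intervals
over ~16 000 years.  After a highly armoured colonist replaced the resident
low-armoured population, the colonist itself evolved reduction in armour,
swimming and feeding traits *in situ*.  Did that gradual change amount to
incipient speciation?  One way to ask is to compare the lineage's
morphological divergence against a modern yardstick: the benthic–limnetic
ecotype pairs of *Gasterosteus aculeatus*, which coexist with strong
reproductive isolation in a handful of British Columbia lakes.

`sticklediv` implements that inference pipeline as a tested, reusable
library for specimen-level trait tables (fossil temporal samples or
lake × ecotype groups, 16 morphological traits, missing values allowed):

* **Armour association** — Fisher's exact test for the joint occurrence of a
  complete pelvis (pelvic score = 3) and three dorsal spines in mixed
  samples.  Because the two traits are controlled by largely unlinked genes,
  a panmictic polymorphic population should show no association; a perfect
  association is evidence of reproductive isolation between co-occurring
  armour morphs.
* **Preprocessing** — single-pass outlier screen (|z| > 3.5 against the
  dataset-pooled mean/s.d., flagged cells set to missing) and allometric
  size correction: per trait, a common slope *b* on standard length with
  group-level random intercepts, corrected value = observed − *b*(stl − L̄),
  keeping values in mm.  Counts and standard length pass through unchanged.
* **Trait-by-trait divergence** — Wilcoxon rank-sum *U* per trait between
  first and last samples, the common-language effect size
  CLES = *U* / (*n*₁·*n*₂) oriented so reduced traits give CLES ≈ 0, and a
  Bonferroni family threshold α = 0.05/16 = 0.003125.
* **Multivariate divergence** — Euclidean distance *d* between group
  trait-mean vectors, a 99-replicate specimen bootstrap for uncertainty, and
  a 99-shuffle permutation test with the add-one rule
  p = (1 + #{d_perm ≥ d_obs})/(P + 1).
* **Comparison and timing** — Welch two-sample *t*-tests between fossil and
  species-pair bootstrap *d* distributions; the trajectory d(first, k) over
  the series; and the earliest age at which the fossil mean ± s.d. interval
  overlaps a reference divergence (generations = years / 2).
* **Correlated trait evolution** — Pearson correlations among per-trait
  temporal mean-vectors, summarized by the off-diagonal mean/s.d./median.

A first-class synthetic-data generator emulates the study system — armour
traits reducing fast then plateauing (the pelvic traits lagging ~3000
years), non-armour traits declining near-linearly, allometric dependence on
a drifting standard length, correlated specimen noise, count rounding, and
per-trait sample sizes between 12 and 67 — and stores the exact ground
truth alongside every table for parameter-recovery testing.

## Worked example

```python
import sticklediv as sd

# synthetic fossil series with known truth
table, truth = sd.generate_fossil_series(sd.default_fossil_params(seed=1))

# preprocess: outlier mask, then allometric size correction
masked = sd.apply_outlier_mask(table, sd.detect_outliers(table))
model = sd.fit_size_correction(masked)
corrected = sd.size_correct(masked, model)

groups = corrected.ordered_fossil_groups()
tt = sd.trait_divergence_table(corrected, groups[0], groups[-1])
rep = sd.divergence_report(corrected, groups[0], groups[-1], seed=1)
print(tt.n_significant, round(rep.d, 2), round(rep.boot_mean, 2),
      round(rep.boot_sd, 2), rep.perm_p, round(truth.true_d, 2))
```

prints

```
12 17.43 17.62 1.37 0.01 19.13
```

i.e. 12 of the 16 traits diverged significantly at the Bonferroni-corrected
threshold; the multivariate distance between the first and last samples is
17.4 (bootstrap 17.6 ± 1.4), no permutation replicate reached the observed
value (p = 0.01, the minimum attainable at P = 99), and the generator's true
divergence 19.1 lies within about 1.2 bootstrap s.d. of the estimate.

The same stages are available from the shell:

```sh
sticklediv run-all --seed 1 --out results_dir
sticklediv simulate fossil --seed 1 --out sim
sticklediv preprocess --in sim/fossil.csv --out-dir prep
sticklediv diverge --in prep/corrected.csv --first K01 --last K18 --seed 1 --out d.json
```

`run-all` writes every stage artifact (masked and corrected tables, size
model, outlier report, trait table, multivariate reports, timing and
correlation summaries) plus a manifest that is bit-identical when rerun with
the same configuration.

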