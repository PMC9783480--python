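# dtmeta

Meta-analysis of sex-specific environmental plasticity in insect development
times.

The unit of analysis is a *primary dataset*: paired male/female mean
development times (days, with standard errors) across two or more treatment
levels of one environmental factor (rearing temperature or larval diet) for
one species. The pipeline computes, per dataset:

* **ln-slope** — the natural log of the reduced-major-axis (RMA) regression
  slope of ln(male DT) on ln(female DT). 0 = proportional (sex-equal)
  plasticity; > 0 = males more responsive; < 0 = females more responsive.
* **SDTD** — signed sexual development-time dimorphism,
  `(longer sex / shorter sex) − 1`, positive when females develop longer,
  averaged over treatments.
* **bootstrap SD / weight** — sampling variability of the ln-slope from a
  uniform-draw bootstrap around each treatment mean (width set by its SE;
  1000 reps), and the inverse-squared-SD meta-analytic weight.
* diagnostics: male–female log-scale correlation (k ≥ 3), gradient length
  (max/min development time).

Effects are pooled with a **phylogenetic multilevel REML model** (species-
level random effect with a Brownian-motion correlation matrix from a Newick
tree, study-level and observation-level random effects, known sampling
variances), with variance partitioning, SDTD meta-regression, per-order
subgroup fits with Holm correction, and **permutation-based inference**:

* overall test — male/female columns swapped within each treatment of each
  dataset, effects and (optionally) bootstrap variances recomputed, model
  refitted;
* moderator test — SDTD values shuffled across effect sizes;
* paired temperature-vs-diet comparison — per-species sign-flip test on
  absolute standardized ln-slopes (exact enumeration available for n ≤ 20).

A first-class synthetic-data module generates Yule trees and full corpora
with known ground truth (phylogenetic signal, study/observation
heterogeneity, SDTD moderation, configurable gradients and noise) for
calibration and recovery testing.

## CLI

```sh
dtmeta simulate -o sim_out --n-species 40 --seed 1      # corpus + tree + truth
dtmeta effects sim_out/corpus.csv -o effects.csv --boot-reps 1000 --seed 1
dtmeta fit effects.csv --tree sim_out/tree.nwk --subgroups -o fit.json
dtmeta paired effects.csv --perms 10000 --std-rule none -o paired.json
dtmeta run-all -c config.yml                            # full pipeline
```

`run-all` reads a YAML config with either an `inputs:` section
(`primary_table`, `tree`, optional `mapping`, optional `dialect`) or a
`simulate:` section (fields of `SimulationConfig`, plus optional
`paired_diet:` overrides), and `bootstrap:`, `permutation:`, `run:` blocks.
See `tests/test_pipeline.py` for working configs. Outputs: `effects.csv`,
reject report, per-trait fits with permutation p-values, subgroup tables,
null-distribution samples, `report.json` and a reproducibility
`manifest.json` (config snapshot, per-stage seeds, input digests, stage
counts).

## Primary-table schema

CSV (UTF-8, header), one row per (dataset, treatment):

```
dataset_id, study_id, species, order_name, trait, factor,
treatment_value, male_mean_dt, male_se, female_mean_dt, female_se
```

`trait` ∈ {total, larval}; `factor` ∈ {temperature, diet}; empty SE cells
mean "not reported" (the dataset is then kept for descriptive summaries but
excluded from the weighted meta-analysis). Column names and decimal commas
are configurable via a table dialect. Trees are Newick; topology-only trees
get Grafen branch lengths (ultrametric, unit depth) before the correlation
matrix is built. A species-mapping CSV (`data_species`, `tree_tip`,
`substitution_kind` ∈ {exact, congener, tribe}) handles tip substitutions.

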