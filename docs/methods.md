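# Methods note

This note records the model definitions, parameter conventions, numerical
choices, and known limitations of the package. It is the reference for "what
exactly does this function compute" questions.

## Data model

Genotypes are integer minor-allele counts in {0, 1, 2}; `-1` encodes a missing
call and is the only missing value the core routines accept. Phenotypes are
binary, 0 = control and 1 = case. CSV/TSV tables carry one subject per row
with a `phenotype` column; PLINK `.raw` export is also read (six leading
metadata columns, 1/2 phenotype coding remapped to 0/1, `_allele` suffixes
stripped from variant names).

## Information-theoretic pair score

All entropies are plug-in (maximum-likelihood) estimates **in bits**
(log base 2). Base 2 was chosen so thresholds have a direct "bits of synergy"
reading; any strictly monotone base change would rank pairs identically. The
convention `0·log(1/0) := 0` applies throughout.

The pair score is

```
IG(u; v; C) = I(u,v; C) − I(u; C) − I(v; C)
```

with the joint genotype treated as one 9-state variable. For a given pair,
all three terms are computed on the same set of subjects with complete data
for `u`, `v`, and `C` (pairwise-complete deletion), so the decomposition is
internally consistent per pair even under missingness. Plug-in IG can be
slightly negative or positive by chance on finite samples; no bias correction
or permutation calibration is applied — the threshold below absorbs the noise
floor.

## Comprehensive network and components

Edges are pairs with `IG > τ`, strictly; the graph keeps no isolated nodes.
Components are selected by size strictly greater than `min_component_size`.
There is no universal τ: the finite-sample null level of IG scales roughly
inversely with sample size. For the synthetic experiments in the tests and
the acceptance script (n ≈ 1000–1600, 20–46 variants) we use **τ = 0.02
bits**, comfortably above the measured noise floor (~0.009 bits at n = 1000)
and far below planted-pair scores (0.15–0.5 bits). `network_profile` exists
precisely so users can pick τ for their own cohort by inspecting node/edge
counts across a grid.

## Subject portraits and the sign rule

For each network edge (u, v), training data yield a 3×3×2 contingency table
of genotype combinations by class. A combination is signed

- `+` if its within-case proportion ≥ its within-control proportion
  (ties → `+`),
- `−` otherwise,
- `absent` if it never occurs in training (default; a `zero_evidence="plus"`
  mode signs unseen cells `+` instead).

Comparing within-class proportions is equivalent to comparing raw counts
after weighting case counts by `n_control/n_case` (equivalently, control
counts by `n_case/n_control`). The implementation makes this equivalence
exact under missingness by cross-multiplying with the per-edge complete-data
class totals, falling back to the proportion comparison if one class has no
complete observations for that edge.

A subject's portrait assigns each edge the sign of their own genotype
combination (`absent` if either genotype is missing or the combination was
unseen in training). The **delta degree** of variant *u* for a subject is
`d⁻(u) − d⁺(u)`; `absent` edges contribute zero. Columns are the network's
nodes in sorted order.

## Evaluation pipeline

- **Cross-validation**: stratified k-fold (shuffled, seeded). The pair
  statistics and therefore the signs are refit on each training fold —
  the transform is part of the model, so it must not see held-out folds.
  The network topology itself is an input (callers decide whether to build
  it inside or outside the split; `holdout_protocol` builds it inside).
- **Classifier**: logistic regression (lbfgs, L2, C = 1.0, max_iter = 1000)
  as the primary model; a 500-tree random forest is available as a baseline.
  Deliberately standard settings — the claim under test is about the
  features, not the classifier.
- **Holdout protocol**: a stratified 80/20 split. Pair scores, the network,
  component selection, pair statistics, and the cross-validated "test"
  estimate all use the 80% only; the final model is refit on the full
  transformed 80% and evaluated once on the untouched 20%. Training-subject
  ids are carried on the fitted statistics so leakage is auditable.
- **Resampling importance**: 100 stratified draws of 80% of each class
  without replacement; statistics, transform, and logistic regression are
  refit per draw; the report gives mean, mean absolute, and standard error
  of each variant's coefficient. Note that because the transform is refit
  on each draw, even null features acquire a shared in-sample association
  with case status; importance should be read *comparatively* across
  variants (does one stand out?), not as a calibrated test against zero.

## Simulator

`simulate_dataset` draws genotypes as Binomial(2, maf) per locus
(Hardy–Weinberg proportions) in linkage equilibrium, applies one or more
penetrance-table disease models whose probabilities combine as
`P(case) = 1 − Π_j (1 − pen_j)`, and fills exact case/control counts by
rejection sampling (seeded, shuffled subject order). Models provided:

- `xor_model(maf, base, lift)`: two-locus parity with penetrance
  `base + lift·parity`; zero main effects at maf = 0.5.
- `threeway_model(maf)`: three-locus parity whose *pairwise* marginals are
  exactly flat — a positive control for what pairwise IG cannot see.
- `pure_epistasis_model(maf, prevalence, heritability)`: penetrance
  `K + c·u uᵀ` with `u = (1, x, 1)` chosen orthogonal to the HWE genotype
  frequencies, giving exactly zero main effects at **any** maf and hitting
  the requested prevalence and broad-sense heritability exactly; it raises
  if the requested (maf, K, h²) would push penetrances outside [0, 1].
  `model_summary` reports the exact prevalence, heritability, and per-locus
  marginal effects of any table.

Scope: the generator covers HWE, linkage-equilibrium, penetrance-table
architectures only. It does not emulate linkage disequilibrium, population
structure, covariates, genotyping-error processes, or quantitative traits.

## Quality control

Variant filters: call rate ≥ 0.99, MAF ≥ 0.05, HWE exact-fit chi-square
(1 df) p ≥ 1e-4 (monomorphic variants get p = 1). Sample filters:
missingness ≤ 5%, heterozygosity within ±3 SD of the cohort mean (computed
before any sample removal). Variant filters run first, then sample filters,
one pass each; reports list every id with the rules it failed.

## Numerical choices

- Entropies via vectorized `bincount` over composite codes (`3a + b` for
  joints); per-pair fallback paths handle missingness.
- Sign tables are 3×3 lookup arrays; the per-subject transform is fully
  vectorized over subjects per edge.
- All stochastic steps take explicit integer seeds (`numpy.random.default_rng`
  or scikit-learn `random_state`); identical seeds reproduce identical
  results, including fold membership.

## Limitations

- Plug-in IG is biased upward on sparse tables; with many variants, τ must
  be set against an empirical or permutation-based noise floor rather than
  at zero.
- Pairwise IG is blind to pure three-way (and higher) interactions by
  construction; the three-locus parity model demonstrates this.
- The all-pairs scan is O(p²) in the number of variants and is intended for
  post-QC candidate sets (hundreds to a few thousand variants), not raw
  genome-wide panels.
- The sign rule conditions on exact genotype combinations; in small cohorts
  many cells are `absent`, which shrinks delta degrees toward zero.
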