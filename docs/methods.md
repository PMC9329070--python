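# Methods

This note documents the models, defaults and numerical choices behind
`pahfate`, and what the synthetic-data tests do and do not demonstrate
about real field data.

## Removal rates

Removal is quantified as the two-point dissolved-phase rate
`r = (C(t0) − C(t1)) / Δt` in ng L⁻¹ h⁻¹, computed per replicate bottle
and summarised as mean ± sd across bottles. The estimator is
deliberately the simple difference quotient used in short bottle
experiments: with only two timepoints nothing more elaborate is
identifiable. Percent decrease is `100·(C(t0) − C(t1))/C(t0)`.
Negative rates (apparent production, usually noise) are preserved and
flagged rather than truncated; truncation would bias class means
upward. Measurements below the limit of quantification cannot enter a
rate; at table level the affected replicate is dropped with a warning,
at scalar level it is an error.

### Benchmark correction

Bottle incubations in small glass volumes lose analytes to walls and
handling in ways shared by all compounds in a bottle. We cancel such
common losses by ratio normalisation to a benchmark compound measured in
the same bottle: per bottle, `s(t) = C_bench(t)/C_bench(t0)` and
`C*_i(t) = C_i(t)/s(t)`. This is a reconstruction of the benchmarking
idea from first principles: ratio normalisation is the simplest
transformation that removes a multiplicative bottle-common loss
*exactly* (a property the test suite asserts to 1e-9), and it leaves the
benchmark's own corrected series constant. The default benchmark is
phenanthrene, appropriate when its removal does not differ between the
habitats being compared (the shipped scenario encodes exactly that
property). Both raw and corrected analyses are available; the benchmark
correction also removes any real biodegradation that the benchmark
itself experiences, so corrected rates are relative to the benchmark's
fate, not absolute.

## Partitioning bound on sorption artifacts

Dissolved concentrations can fall without biodegradation if compounds
re-equilibrate into growing organic-matter pools. We close a three-pool
equilibrium mass balance in a fixed volume:

- biota pool `B` (kg organic matter / L), with bioconcentration factor
  `BCF = f_OM · 10^(log Kow) / δ` (L/kg),
- DOC pool `D` (kg C / L), with `K_DOC = 0.1 · 10^(log Kow)` (L/kg),
- dissolved fraction `f_diss = 1 / (1 + BCF·B + K_DOC·D)`, the sorbed
  fractions following by closure (they sum to 1 to machine precision).

The repartitioning bound between two timepoints is
`max(0, 1 − f_diss(t1)/f_diss(t0))`: the largest share of an observed
dissolved-phase decrease that pool growth alone could produce. It is
floored at zero because shrinking pools cannot explain a decrease.

Defaults and units: octanol density δ = 0.82 kg/L; `f_OM` = 1 applied to
an organic-matter mass basis; bacterial biomass from cell counts at
20 fg C cell⁻¹ and an OM:OC mass ratio of 2.0; phytoplankton biomass
added directly as kg OM/L; DOC 60 µM C (a typical Antarctic surface
value) converted at 12.011 g/mol. Every constant is configurable, and
`log Kow` values ship as literature defaults in an editable CSV because
downstream results depend on them monotonically, not on their exact
decimals. There is a single pooled biota pool (no separate phytoplankton
BCF) and no kinetic sorption model: over 24 h at these length scales the
equilibrium assumption is the conservative choice for an *upper bound*
on the artifact.

### Attribution rule

Per compound: `NO_REMOVAL` if the percent decrease is within a noise
threshold (default 2 %, configurable); `SORPTION_POSSIBLE` if the
repartitioning bound (×100) covers the decrease, compared with a 1e-9
percentage-point tolerance so that a decrease exactly equal to the bound
— the signature of pure repartitioning — is never called biodegradation;
`BIODEGRADATION_DOMINANT` otherwise.

## Statistics

- **Mann–Whitney U**, two-sided. For pooled samples of ≤ 12
  observations (the regime of these experiments) the p-value is exact:
  complete enumeration of all C(n1+n2, n1) assignments of the pooled
  mid-ranks, counting assignments whose U is at least as far from
  n1·n2/2 as observed. Mid-ranks make U a multiple of 0.5, so the
  comparison has no rounding ambiguity. Ties are handled by enumerating
  over the tied data as given (the conservative convention). Above the
  threshold, the tie-corrected normal approximation with continuity
  correction is used (via scipy).
- **t-tests**: Welch's unequal-variance test for unpaired comparisons,
  the paired test on request; zero variance of paired differences is a
  degenerate-data error, not a p-value.
- **Fold changes** follow the gtools sign convention: `a/b` if `a ≥ b`,
  else `−b/a`; magnitude always ≥ 1, antisymmetric under argument swap,
  undefined (error) for non-positive inputs.
- No multiple-testing correction is applied by default (raw p ≤ 0.05 is
  the convention in this experimental niche, with few planned
  contrasts); a Benjamini–Hochberg helper is provided for users who
  screen many taxa.
- Layer comparisons are offered with two pooling conventions — per
  weight class across compounds × replicates (plus the per-replicate
  HMW sum), or per compound — because with two bottles per condition a
  per-compound exact test cannot reach p < 0.05 by itself.

## HCB screen

Rarefaction draws a multivariate hypergeometric sample per column
(subsampling without replacement), which preserves expected proportions
exactly and reproduces bit-identically for a fixed seed; samples below
the target depth are dropped with a warning; the default depth is the
minimum sample sum. Counts are aggregated to genus rank (taxa
unassigned at that rank pool into an `unclassified` bin that never
matches the HCB list), converted to per-sample proportions, and
restricted to a curated HCB genus list shipped as an editable text file.
Genus-level matching assumes ASVs within a genus share
hydrocarbon-degrading metabolism — a useful screening assumption, not a
guarantee. Archaea are dropped before analysis by default (toggleable).
In the treatment-vs-control comparison, a taxon with zero mean
abundance in one arm uses a pseudo-proportion of half the smallest
nonzero proportion in the stratum, since the fold-change ratio is
undefined at zero.

## Synthetic data: what it emulates, and what it does not

The incubation generator evolves total mass per bottle and compound as
`exp(−(k_bio + k_wall)·t)` and reports the dissolved fraction of it,
times mean-one lognormal noise (`σ² = ln(1 + CV²)`, default CV 10 %).
The generative truth is first-order decay even though the pipeline
estimates a linear two-point rate — intentionally, so the tests measure
the estimator's behaviour rather than assume its model. Controls start
at an in-situ background (default 0.5 ng/L per compound); abiotic
bottles (wall loss only, no pools) are available.

The shipped reference scenario encodes the qualitative pattern the
pipeline is designed to resolve: SML HMW rates spanning 0.29–3.08
ng L⁻¹ h⁻¹ (increasing with hydrophobicity; rank-spacing exponent 1.145
sets the class mean to ≈ 1.6), SML LMW rates 0.03–0.25 (mean 0.14), SSL
LMW rates averaging 0.17 with phenanthrene removed identically in both
layers (which is what qualifies it as the benchmark), and SSL HMW rates
of zero. Organic-matter pools are constant in time there, so any
sorption-artifact signal is absent by construction; a separate
sorption-only configuration (biodegradation off, biomass doubling)
exercises the attribution bound.

The community generator draws Dirichlet-multinomial counts around a
fixed composition: HCB genera at explicit baseline proportions, decoy
taxa filling the rest with lognormal weights, and selected HCB genera
multiplied by an enrichment factor in exposed arms before
renormalisation. Renormalisation compresses the realised proportion
ratio to `f/(1 + p0·(f−1))` — an 8× factor on a 2 % genus realises
≈ 7.0× — and `true_fold_change` reports that realised truth. The
Dirichlet concentration defaults to 500, i.e. a between-replicate CV of
roughly 15–30 % for few-percent taxa, matching the replicate precision
reported for duplicate bottles in the experiments this emulates; it is
configurable for noisier designs.

Passing tests on these simulations demonstrate estimator correctness
and statistical calibration *under the generative assumptions*
(independent lognormal measurement error, equilibrium partitioning,
exchangeable replicates, no compositional interactions between taxa
beyond renormalisation). They do not validate GC-MS chemistry, primer
or extraction biases, chimera/ASV inference, or taxonomy assignment —
all upstream of this package.

### Known estimator limits quantified by the tests

With independent 10 % measurement noise on both endpoints, the sd of a
two-point rate is `CV·sqrt(C0² + C1²)/(Δt·√n_rep)` ≈ 0.8 ng L⁻¹ h⁻¹ at
a 200 ng/L spike with duplicate bottles — larger than many true rates
in the reference pattern. Per-compound rates below ~1 ng L⁻¹ h⁻¹ are
therefore individually unreliable at this design size; the pipeline's
robust outputs are class-pooled summaries and rank-based layer
contrasts, which the multi-seed tests show are stable (pooled HMW
contrast detected in ≈ 99 % of simulations, LMW correctly
non-significant in ≈ 96 %). The acceptance suite states this honestly:
the per-compound median relative error under noise is measured and
reported rather than hidden, and it exceeds what duplicate bottles can
deliver.

## Numerical and interface choices

- Determinism: every stochastic routine takes a seed; fixed seed ⇒
  byte-identical outputs (asserted in tests). Simulation CSV/TSV
  outputs record the seed in a `#` header line; the report embeds
  SHA-256 hashes of its inputs and no timestamps, so re-runs on equal
  inputs are byte-identical.
- Strict column validation on all inputs; errors name the offending
  column/bottle. CLI exit codes: 0 success, 2 input error,
  3 degenerate statistics.
- Problem sizes in the test and acceptance runs (100 simulation seeds
  for the contrast and enrichment properties, 500 datasets for the
  exact-test oracle, 200 seeds for rarefaction bias, 1,000 draws for
  mass balance) were chosen to make Monte-Carlo error small relative to
  the asserted margins while keeping a full run in tens of seconds.
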