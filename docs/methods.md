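# Methods

## Scope and data model

`stromascan` operates on a genes × samples expression matrix on log2 scale
(RNA-seq values log2-transformed after addition of 1, or microarray
log-intensities collapsed to one probe per gene) together with a clinical
table holding overall-survival time and event plus stratification
covariates (ER status, node status, age group, stage group, tumor size
group). Time units are carried as metadata and never converted implicitly.
Microarray probe collapsing keeps, for each gene, the probe with the
maximal mean signal across all samples of the cohort (ties broken toward
the lexicographically smaller probe id); "maximal signal" is not otherwise
standardized, and the per-cohort mean is deterministic and scanner-free.

## Metagene construction

Candidate expansion selects every gene whose Pearson correlation (computed
on log2 values across all samples) with at least one seed gene strictly
exceeds `r_expand` (default 0.84). Greedy compaction then iterates: each
gene's mean correlation with the *other* genes in the current set is
computed (self-correlation excluded — including it would inflate means by
(1 − r̄)/k and change which thresholds are attainable); if the minimum is
≤ `r_compact` (default 0.85, strict), the argmin gene is removed and the
loop repeats. Equal minima are broken toward the lexicographically smallest
symbol so runs are reproducible. The full removal trace (gene, mean r at
removal) is returned, and an unattainable threshold (set would shrink below
`min_size`, default 2) raises an error carrying the trace so near-misses
can be inspected. Compaction output is always a subset of its input and is
idempotent; both properties are asserted in the test suite, and the whole
procedure is checked for exact agreement (surviving set and removal order)
against an independently coded step-by-step oracle on random instances.

Consensus across cohorts is a plain set intersection ordered by the first
signature. Tumor scoring is the standardized mean: per-sample mean of the
signature genes' log2 values, then standardization across samples
(n − 1 denominator), giving mean 0 / SD 1 by construction. An alternative
order of operations — z-score each gene first, then average — is available
behind `per_gene_standardize=True` (it weights genes equally regardless of
their variance); the default is mean-then-standardize, and the returned
vector is standardized in both modes.

## Stratified Cox fitting

The partial likelihood is maximized per stratum (each stratum contributes
its own risk sets; no baseline hazard is estimated) with Efron's correction
for tied event times, the default of the standard survival tooling this
package is meant to interoperate with. Optimization is Newton–Raphson with
step-halving on overshoot, relative log-likelihood tolerance 1e-9, at most
100 iterations; a singular information matrix, failed step-halving, or a
coefficient magnitude above 50 (complete separation) flags the fit
unconverged rather than raising. Sorting, tie grouping and the Efron
fractions depend only on (time, event, strata), so they are precomputed
once per design and reused across covariate matrices — the exhaustive pair
scan performs C(n,2) two-covariate fits against one precomputed design at
roughly a millisecond per fit. Coefficients, standard errors and
log-likelihoods agree with `lifelines.CoxPHFitter` (also Efron) to ~1e-5
on tied, stratified data; a grid-search oracle over the partial likelihood
confirms the tiny-n case. Eta values are centered within stratum before
exponentiation for overflow safety (the partial likelihood is invariant to
per-stratum location shifts).

Samples with a missing value in any stratification field are excluded from
fits, with the count logged. The default scan stratification is the
cross-product of ER × node status; signature evaluations accept any
configured strata (e.g. age × stage for cross-cancer comparisons) —
nothing is hard-coded.

## Pair scan and signature derivation

All unordered pairs of candidate genes enter a two-covariate stratified Cox
model using raw (unstandardized) log2 expression; single-gene evaluations
use standardized log2 expression, and signature-level evaluations use the
centered per-sample mean of the member genes' log2 values. Pairs are ranked
by the likelihood-ratio test of the two-covariate model against the null
model within identical strata (χ², df = 2); unconverged pairs sort last and
are flagged, never silently dropped. Derivation takes the first `top_k`
(default 100) converged pairs, counts gene appearances, keeps genes
appearing strictly more than `min_count` (default 5) times, and classifies
each kept gene by the majority sign of its hazard ratios across its
appearances (HR > 1 → poor set, HR < 1 → good set); exact sign ties are
excluded with a warning. On synthetic cohorts the top-ranked pairs are
empirically all opposing-HR pairs, so no explicit opposing-sign filter is
applied before ranking.

## Synthetic cohort generator

A latent fibroblast-abundance factor F ~ N(0, 1) (optionally shifted upward
in ER-positive tumors by `er_effect_on_stroma`, default 0.3) drives the
stromal block: gene i = μ + λF + σε with μ = 8, λ = 3, σ = 1 on log2 scale,
giving inter-gene correlation λ²/(λ² + σ²) = 0.9, typical of compact
stromal clusters. An endothelial factor E = ρF + √(1 − ρ²)ε (default
ρ = 0.6, within the 0.34–0.78 range observed across tumor types) drives an
endothelial block the same way. Two prognosis-relevant components
G = a_G F + √(1 − a_G²)η and P (analogous) are both positively correlated
with stroma (defaults a_G = a_P = 0.7); planted good/poor genes load on
them with the same tightness as the stromal block. Survival follows a
proportional-hazards model with linear predictor β_good·G + β_poor·P
(defaults −0.5 / +0.5), exponential baseline (default rate 0.02 per month,
optional per-stratum multipliers) sampled by inverse transform, and
independent exponential censoring whose rate is solved with Brent's method
so the expected censored fraction hits the target (default 0.3).

Scan-candidate background genes are modeled as stromal candidates: they
load on F with small heterogeneous spillover onto G and P (per-gene tilts
~ N(0, 0.3)). This mirrors what a correlation-expanded candidate set
actually is — a continuum of stroma-correlated genes carrying varying
amounts of each transcriptional program — rather than pure noise, and it is
what makes the two-sided signature discovery reproducible: with strictly
independent background genes, each planted gene can appear in at most five
top-ranked opposing pairs (one per opposite-side partner), and the strict
"more than five appearances" rule then keeps only the side whose latent
association happens to be stronger in that cohort draw.

Expression is generated on log2 scale, converted to linear as 2^y − 1 and
stored as log2(linear + 1) — an exact round trip that exercises the same
load path as real data (log2 values are clipped at 0 first; with the
default μ = 8 this affects well under 1% of draws). Everything is a pure
function of (config, seed).

What the generator does **not** emulate: TCGA-like marginal distributions,
library-size or batch effects, probe-level noise, non-proportional hazards,
informative censoring, and the heavy (~85%) censoring of real TCGA
breast-cancer follow-up — synthetic cohorts use a 30% censoring default so
that effect recovery is measurable at the simulated sample sizes. Passing
tests therefore demonstrate correctness of the algorithms under the assumed
latent-factor structure, not performance on real cohorts.

## Validation experiments and problem sizes

The acceptance script and test suite run: greedy-compaction oracle
agreement (100 instances, ≤ 12 genes, 100 samples); Cox coefficient
recovery (200 cohorts, n = 500, β = ±0.5, 30% censoring — mean |bias|
< 0.05, CI coverage ≈ 95%); LRT null calibration (2000 replicates, df = 2,
n = 300 — rejection ≈ 5% at nominal 0.05); planted-signature recovery
(20 cohorts, n = 800, 50 candidates — fraction of planted genes recovered
on the correct side, and the fraction of cohorts with zero wrong-side
placements); the amplification phenomenon (20 cohorts — both signatures'
joint |log HR| exceeding their univariate values); metagene-score
standardization (1e-9); and RPKM per-sample sum conservation (1e-9
relative). The recovery experiment's mean sits near 0.8 with
seed-batch-to-seed-batch variation of a few points; the zero-wrong-side
property is robust (30/30 measured batches).

## Known limitations

* The pair scan applies no multiple-testing correction; it is explicitly
  explorative, and derived signatures must be validated on independent
  cohorts.
* Proportional-hazards diagnostics (Schoenfeld residuals), time-varying
  covariates and competing risks are out of scope.
* The Cox fitter targets small covariate counts (1–4); it makes no attempt
  at penalization or high-dimensional scaling.
* Stratification with many sparse strata silently loses information
  (single-observation strata contribute nothing); the fitter does not warn
  about this beyond the excluded-sample log line.
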