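# Methods

This note documents the statistical models implemented in `lifemr`, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions.

## Summary-statistics model

All inference operates on per-variant association records
(β̂, SE, Z, p, EAF, n). Where a release carries only Z-scores, effects
are recovered on the standardized per-allele scale as

    SÊ = 1 / sqrt(2·p·(1−p)·(n + Z²)),    β̂ = Z · SÊ,

with p the effect-allele frequency. This SE is *minimized* at p = 0.5
and strictly decreasing in n. Lifespan effects are on the
−logₑ(Cox hazard ratio) = logₑ(protection ratio) scale; years of life
per unit effect are 10× that quantity. p-values are recomputed from Z
as two-sided standard-normal tails; a stored p is retained only where a
filtering decision was originally made on the reported value.

Positions are 1-based and all genomic windows are closed intervals.
BED exports convert to 0-based half-open coordinates.

### Harmonization

Two-sample MR requires exposure and outcome effects per the same
allele. Matching allele pairs are kept; swapped pairs negate the
outcome effect and complement its frequency. Palindromic variants
(A/T, C/G) cannot be oriented from alleles alone; the default policy
keeps them only when both allele frequencies are on the same side of
0.5 and outside [0.4, 0.6], and otherwise excludes them with a counted
reason. Source studies rarely state their harmonization rules; this
one is declared, not inferred, and is switchable (`strict`/`drop`/`keep`).

### Gaussian imputation

Unobserved Z-scores are imputed as the conditional mean under the
multivariate-normal model with LD correlation Σ:
ẑ_t = Σ_tu (Σ_uu + λI)⁻¹ z_u, with per-target quality
r² = Σ_tu (Σ_uu + λI)⁻¹ Σ_ut. The ridge λ = 0.1 (default) keeps the
observed block invertible when reference LD is collinear; λ = 0 gives
exact interpolation of perfectly tagged variants.

## Locus definition

FUMA-style vocabulary: independent significant SNPs are genome-wide
significant variants (p < 5×10⁻⁸, MAF ≥ 0.01) greedily pruned in
ascending p at r² < 0.6; candidates are all MAF-filtered variants at
r² ≥ 0.6 with any of them; lead SNPs re-prune at r² < 0.1; loci whose
spans are separated by < 250 kb merge transitively, the merged lead
being the member lead with the smallest p. Greedy traversal in
ascending p with a deterministic tie-break (p, chrom, pos, id) makes
the selection order-independent. SNP–gene distance is measured to the
TSS; pairs are cis at ≤ 1 Mb, trans beyond 5 Mb or across chromosomes,
and the 1–5 Mb zone is reported as `unclassified` rather than silently
assigned to either class.

## Two-sample MR

With harmonized per-instrument effects (β̂Xⱼ, β̂Yⱼ) and wⱼ = SE(β̂Yⱼ)⁻²:

- **Wald ratio** θ̂ⱼ = β̂Yⱼ/β̂Xⱼ, SE = SE(β̂Yⱼ)/|β̂Xⱼ| (first-order: the
  exposure uncertainty is ignored, matching the IVW weighting; no
  second-order correction).
- **IVW** θ̂ = Σwⱼβ̂Xⱼβ̂Yⱼ / Σwⱼβ̂Xⱼ², algebraically the weighted
  least-squares slope through the origin. The default model is
  *multiplicative random effects*: the fixed-effect SE is inflated by
  max(1, √(Q/(J−1))) — never deflated. Fixed-effect is available by
  flag. Estimate p-values use the normal reference (J is moderate in
  practice and this matches common package behaviour).
- **Cochran's Q** = Σwⱼ(β̂Yⱼ − θ̂β̂Xⱼ)², df = J−1, χ² upper tail.
  Heterogeneity is declared at p < 0.05.
- **MR-Egger** orients instruments to β̂Xⱼ ≥ 0 and fits a weighted
  regression with intercept; the intercept estimates average
  directional pleiotropy (absence declared at p > 0.05), the slope is
  the pleiotropy-adjusted causal estimate; SEs carry the same
  multiplicative inflation with df = J−2.

A note on calibration: under the homogeneous null the fixed-effect IVW
p-value is exactly uniform, while the floored random-effects variant is
conservative by construction (its measured level is ≈ 0.043 at
α = 0.05). Calibration checks in the test suite therefore exercise the
fixed-effect model, which is the generating model under that null; the
floored inflation is a deliberate robustness default for real data,
where heterogeneity is the rule.

### Decision logic

Within a family of m tested genes, a gene is called causal iff its IVW
p passes the Bonferroni gate (p < α/m, e.g. 0.05/116 = 4.3×10⁻⁴) and
either (a) Cochran's Q shows no heterogeneity (p ≥ 0.05), or (b) it is
rescued by MR-PRESSO. Each call carries its evidence path; a
heterogeneous significant gene with no PRESSO result is flagged
incomplete rather than called.

## MR-PRESSO

- **Global test**: leave-one-out IVW slopes θ̂₋ⱼ give the observed
  residual sum RSS = Σⱼ(β̂Yⱼ − θ̂₋ⱼβ̂Xⱼ)²; parametric replicates redraw
  β̂Xⱼ* ~ N(β̂Xⱼ, SEXⱼ), β̂Yⱼ* ~ N(θ̂₋ⱼβ̂Xⱼ, SEYⱼ) and are scored by the
  same statistic. n_sim defaults to 1000; all empirical p-values use
  (1 + #exceedances)/(n + 1) and so floor at 1/(n_sim+1), never 0.
- **Outlier test**: per-instrument pⱼ from the simulated residual²
  distributions, Bonferroni-corrected by J; outliers at corrected
  p < 0.05. Removal is single-pass (no iterative re-testing).
- **Distortion test**: the corrected estimate is IVW on the
  non-outliers; the distortion coefficient is the percent change from
  the all-instrument estimate; its null removes equally many uniformly
  random instruments (without replacement). Observed and null
  coefficients are computed by one shared incremental expression (with
  sorted indices) so that a null draw removing exactly the outlier
  subset ties bit-for-bit — the tie mass at the observed value is part
  of the two-sided empirical p. If the all-instrument estimate is
  exactly 0 the coefficient is undefined and flagged.
- **Gating** (rescue of an IVW-significant heterogeneous gene):
  proceed only if Global p < 0.05 and ≥1 outlier is found; the rescue
  succeeds iff corrected-IVW p < 0.05 and Distortion p > 0.05. Note a
  *single* gross outlier is rarely rescuable under this gate — its
  removal distorts the estimate more than random removals do — whereas
  sign-balanced pleiotropy (which inflates Q without biasing the
  slope) is the configuration the gate is designed to pass.

Every result records its seed; identical seeds reproduce every field.

## Colocalization

Per-variant evidence is the Wakefield approximate Bayes factor,
log ABF = ½(log(1−r) + r·Z²) with r = w/(SE² + w); the prior effect
variance w defaults to 0.15² for quantitative and 0.2² for binary
traits. The five-hypothesis posterior uses per-variant priors
p1 = p2 = 10⁻⁴ and p12 = 10⁻⁵ (standard defaults; the source analyses
state none) with all sums in log space (log-sum-exp; the H3 term uses a
stable log-difference and is −∞ for single-variant regions). A shared
signal is called at PP(H4) > 0.8. More than two traits are composed
pairwise into clusters (connected components over PP(H4) > 0.8 edges);
this is an explicit approximation to a joint multi-trait analysis, not
a reimplementation of one. The model assumes at most one causal
variant per trait per region; regions with several causal variants can
legitimately favour H3 even when all of them are shared.

## Network and enrichment statistics

Hypergeometric over-representation is exact (upper tail P(X ≥ k)),
with fold = (k/n)/(K/N); only over-representation is tested.
Betweenness is exact unnormalized Brandes on the unweighted simple
graph, each unordered pair counted once. "Top percentile" membership is
*strictly above* the linear-interpolation 0.99 quantile, so ties at the
threshold (and constant vectors) are excluded. Disease–disease networks
connect diseases sharing a gene, edge weight = number of shared genes;
total weight equals Σ_g C(d_g, 2). Concordance labels a
disorder/lifespan effect pair concordant when the signs oppose (lower
risk ↔ longer life), with significance tiers nominal / BH-FDR /
Bonferroni assigned by the disorder association p.

## Synthetic data

Generators work at the Z-score level: for LD matrix R and standardized
joint effects b, marginal Z-scores are N(√n·R·b, R). This is exact for
every summary-statistics method above and fast enough for
calibration-scale simulation, but it deliberately has no
population-genetic realism: no MAF–LD coupling, no selection, no
genotype data. Passing tests therefore demonstrate the statistical
machinery, not robustness to real-data pathologies (allele-frequency
mismatch between panels, strand ambiguity at scale, sample overlap).

- `sim_ld` — AR(1) correlation (r_ij = ρ^|i−j|); block-diagonal
  composition for multi-signal loci.
- `sim_mr_dataset` — harmonized instrument sets: |β̂X| ~ U(0.05, 0.2)
  (bounded away from 0), SE_X ~ U(0.005, 0.015), SE_Y ~ U(0.003, 0.01),
  pleiotropy αⱼ ~ N(μ, σ²), planted outliers in units of the
  instrument's outcome SE. Exposure effects are positive by default so
  a directional pleiotropy mean is identifiable by Egger after
  orientation (a `sign_mix` flag restores mixed signs).
- `sim_coloc_region` — null / shared / distinct / one-trait scenarios;
  the causal joint effect is scaled so the expected marginal Z at the
  causal variant equals `z_target`; distinct causal variants are placed
  so their LD r² < 0.01.
- `sim_network` — degree-proportional attachment (or uniform G(n,m))
  with an exact edge count.
- `sim_study` — a complete eQTL + GWAS study for the end-to-end
  pipeline: 50 genes with TSSs 3 Mb apart, each locus eight independent
  AR(1)(ρ=0.8) blocks of six variants with one causal eQTL per block at
  expected |Z| = 40 (strong cis-eQTL scale), n_exposure = 31,684,
  n_outcome = 10⁶, causal slopes ±0.03 (alternating signs) for the
  first five genes. This geometry makes the instrument filter
  (p < 10⁻³, r² < 0.1) select exactly the eight causal variants as
  mutually independent instruments, and keeps exposure measurement
  error below 3% of the outcome residual variance so Cochran's Q stays
  near its nominal level for clean genes. One causal gene carries an
  opposite-sign pleiotropy pair (±5 outcome-Z units) — heterogeneous
  but rescuable by construction. A fraction of GWAS records is written
  with swapped alleles to exercise harmonization. Because the Q test
  false-flags clean genes at its nominal 5% rate (and chance flags are
  only sometimes recovered by a legitimate PRESSO rescue), exact
  recovery of all five planted genes is realized in roughly two thirds
  of study seeds; the bundled end-to-end check runs a seed at which the
  planted structure is realized.

## Problem sizes

Calibration checks use 2000 simulated genes (J = 26) and binomial 99%
confidence bands; recovery means use 1000 replicates against 3
Monte-Carlo SEs; MR-PRESSO operating characteristics use 200 replicates
at n_sim = 1000; colocalization scenario rates use 200 replicates of
200-variant regions; the end-to-end study uses 50 genes × 48 variants.
These sizes were chosen so the whole suite runs on a single CPU in a
few minutes while leaving the binomial/Monte-Carlo bands meaningful.

## Known limitations

- No Steiger directionality filtering, no weighted-median/mode or
  multivariable MR estimators.
- First-order Wald SEs (NOME assumption); with weak instruments and a
  nonzero slope, exposure noise mildly inflates Q — quantified and
  controlled in the synthetic designs, unavoidable in real data.
- Single-causal-variant colocalization; no LD-aware multi-causal
  extension, no fine-mapping.
- LD is consumed, never estimated; no VCF/BGEN handling, no liftover.
- The pairwise multi-trait composition can chain clusters through
  intermediate traits (transitivity is not guaranteed by the pairwise
  posteriors themselves).
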