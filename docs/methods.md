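# Methods

## Model and assumptions

All estimators operate on summary-level two-sample MR data: for variant j,
an exposure association γⱼ with standard error σ_xj and an outcome
association Γⱼ with σ_yj, measured in non-overlapping samples. Instruments
are assumed (1) associated with the exposure, (2) independent of
confounders, and (3) to affect the outcome only through the exposure; the
sensitivity battery probes violations of (3). Binary-outcome effects are
treated as log-odds throughout and converted to odds ratios only at
reporting.

**IVW.** Weighted regression of Γ on γ through the origin, weights
1/σ²_yj. The default multiplicative random-effects variant multiplies the
fixed-effect SE by max(1, σ̂), σ̂² = Q/(J−1): over-dispersion widens the CI,
under-dispersion never narrows it below the fixed-effect SE. p-values are
normal. The fixed-effect variant is available (`effects_model="fixed"`).

**MR-Egger.** After orienting every variant so γⱼ > 0, weighted regression
with a free intercept (average directional pleiotropy). SEs carry the same
max(1, σ̂) inflation; p-values use t with J−2 df. The intercept test
assumes the instrument effects are measured essentially without error
(NOME): when the spread of true γ across instruments is not large relative
to σ_x, the test is anti-conservative — this is a property of the method,
and the calibration study therefore uses a large exposure GWAS
(n = 500,000) so NOME holds.

**Weighted median / weighted mode.** Ratio estimates βⱼ = Γⱼ/γⱼ with
first-order weights γⱼ²/σ²_yj. The median interpolates the weighted
empirical CDF at 0.5 (cumulative midpoints Sⱼ = Σᵢ≤ⱼ w′ᵢ − w′ⱼ/2); the mode
maximizes a normal-kernel-smoothed weighted density over the ratio points,
bandwidth h = φ·0.9·min(sd, IQR/1.349)·J^(−1/5), φ = 1 by default. Both
take SEs from a parametric bootstrap (γ*ⱼ ~ N(γⱼ, σ_xj),
Γ*ⱼ ~ N(Γⱼ, σ_yj); default 1,000 replicates, explicit seed, one stream per
call, bit-reproducible).

**Cochran's Q.** Q = Σ wⱼ(Γⱼ − fitted ⱼ)² about the IVW (df J−1) or Egger
(df J−2) fit; chi-square upper tail. Q = (J−1)σ̂² of the IVW
random-effects fit by construction.

**MR-PRESSO.** The observed statistic is the weighted residual sum of
squares about leave-one-out IVW fits. Its null distribution is simulated
by redrawing (γ*, Γ*) from the sampling model around the leave-one-out
fitted values; empirical p-values use (1 + hits)/(1 + n_sim) so they are
never exactly zero (this stabilizes downstream FDR). The outlier test
compares each variant's observed residual with its own simulated
distribution, Bonferroni-adjusted over J — note the adjusted-p floor
J/(n_sim+1) means n_sim must exceed J/α for the outlier test to have any
resolution (with J = 30 and α = 0.05, n_sim ≥ 1,000 — the default). The
distortion test is implemented as a label permutation of the outlier set
(the commonly circulated description of the original bootstrap is
ambiguous; the permutation version is exactly specified and deterministic
here). Random draws are keyed to variants sorted by identifier, so results
are invariant to input row order.

**Steiger.** Per-variant filtering drops variants whose variance explained
on the outcome (r² = t²/(t² + n − 2), from p and n) exceeds that on the
exposure; exact ties are kept and flagged. The whole-set directionality
test compares Fisher-transformed √R² totals at the two sample sizes with a
normal test.

**Instrument strength.** F = [R²(n−k−1)] / [k(1−R²)], evaluated both
per-variant (k = 1) and for the aggregate set (R² = sum of per-variant r²;
residual LD below the clumping threshold r² < 0.001 is ignored). Variants
or sets with F < 10 are removed.

**Harmonization.** Identifier-keyed (sources are rsID-keyed); swapped
alleles negate the outcome beta and reflect its frequency; strand
complements are retried through the same rules. Palindromic variants are
kept only when both frequencies are on the same side of 0.5 and outside
0.5 ± 0.08 (window configurable); a missing frequency drops them. These
rules mirror common harmonization practice; they are explicit package
choices since screening protocols rarely print them.

**Outcome-overlap exclusion.** Instruments with outcome p < 0.05 are
excluded before estimation, with p recomputed as 2·Φ(−|Γ/σ_y|) so the rule
also applies to tables lacking a p column (a warning is logged when a
stored p disagrees by more than 10% on the z scale). This threshold is far
more aggressive than the conventional 5×10⁻⁸; it is the screening
protocol's printed rule, so it is the default, but it is configurable. Two
consequences worth knowing: in high-powered settings it removes genuinely
causal instruments, and conditioning on |z_outcome| < 1.96 attenuates the
surviving Γ and hence the causal estimate. The end-to-end tests and the
worked example show exactly this attenuation.

**FDR tiering.** Benjamini–Hochberg within exposure class (family
configurable): FDR < 0.1 significant; P_IVW < 0.05 with FDR ≥ 0.1
suggestive; otherwise null.

**Mediation.** indirect = a·b with SE √(a²SE_b² + b²SE_a²); direct =
c − a·b (exact identity with the total); proportion = 100·a·b/c with two
SEs reported: the ratio delta SE |prop|·√(SE²_ab/(ab)² + SE²_c/c²)
(used for the CI) and the numerator-only SE 100·SE_ab/|c|, since screening
reports differ in which they use. No covariance terms: the three effects
come from separate samples. Step B is univariable mediator→outcome MR (not
multivariable MR adjusting for the exposure) — a known limitation of the
two-step formulation: when the exposure affects the outcome through the
mediator's instruments, b can be contaminated. Proportions outside
[0, 100]% and sign-inconsistent mediation are reported as computed and
flagged, never truncated.

**LDSC-lite.** Single-step WLS of χ² (and z₁z₂) on LD scores with weights
1/max(ℓ, 1); h² = slope·M/N, ρ_g = slope·M/√(N₁N₂), r_g = ρ_g/√(h²₁h²₂).
Deliberately simplified — no block jackknife, no two-step intercept
constraint, no stratification — adequate for synthetic parameter recovery;
it is not a reimplementation of the full published LDSC. Negative
heritabilities are reported and flagged; r_g is clamped to [−1, 1] only in
the report column.

**Enrichment.** Upper-tail hypergeometric per pathway against a compound
universe, BH-FDR across pathways, raw p < 0.01 marked significant.

## Synthetic data generator

Summary statistics are generated directly at the summary level: per-variant
sampling SE σ = 1/√(2·maf·(1−maf)·n) on a standardized-trait scale, and
observed effects drawn N(truth, σ). This reproduces exactly the sampling
model the estimators assume, at a tiny fraction of the cost of
individual-level simulation. What it does **not** reproduce unless
explicitly switched on: winner's curse (``selection_threshold`` re-draws
selected instruments conditional on passing) and sample overlap
(``overlap_rho`` correlates exposure/outcome noise). Passing tests
therefore demonstrate correctness of the estimators under their own
sampling model, not robustness to those artifacts.

The triplet generator (`simulate_triplet`) lays variants in AR(1) LD
blocks (block size 10, within-block correlation 0.5 by default), puts a
true effect on the lead of each of the first `j_causal` blocks (each
explaining `per_variant_r2` = 0.003 of exposure variance, so a
1×10⁻⁵-threshold screen at n = 8,000 retains them with F ≈ 20–25), and
propagates effects within blocks by the AR(1) correlation. Mediator-specific
instruments occupy the following blocks. Allele pairs are drawn
non-palindromic so harmonization is exercised without stochastic loss.

Default sample sizes (n_exposure = n_mediator = 8,000; n_outcome = 5,000
effective) emulate the screening regime the protocol was designed for:
small microbiome/metabolite GWAS against a binary outcome whose per-variant
associations are weak. The outcome size is deliberately an *effective* size
on the observed log-odds scale, chosen so per-instrument outcome z-scores
stay mostly below 1.96 — the regime in which the printed outcome-overlap
exclusion retains most instruments. At face-value biobank sizes that rule
empties every truly causal instrument set, which is the main reason the
generator does not default to them.

Two fast helpers generate already-harmonized pairs for calibration studies
(`simulate_pair`, `simulate_chain_pairs`), skipping table construction and
harmonization per replicate; the heavier studies (2,000 replicates) use
them. `orient_positive` fixes the allele labelling so all true exposure
effects are positive — required for directional pleiotropy to remain
directional in ratio space; `pleiotropy_relative` draws direct effects as
multiples of each variant's outcome SE, keeping them heteroscedasticity-
matched to the sampling noise.

## Numerical choices and degenerate inputs

- Empirical p-values: (1 + hits)/(1 + n) everywhere.
- Clumping ties on p broken lexicographically by variant id.
- All-identical Wald ratios: every estimator returns that ratio; the mode's
  bandwidth degenerates to zero and short-circuits.
- J = 1 pairs fall back to the single-instrument Wald ratio in the screen;
  J = 0 yields status `skipped_no_instruments`. Per-exposure failures
  downgrade to skipped rows; they never abort a screen.
- p-values from simulated z-scores are floored at 1e-320 to stay in (0, 1].
- Screens derive one sub-seed per trait pair from (run seed, trait ids) via
  CRC32, so adding or reordering exposures does not perturb other rows.

## Problem sizes in the shipped studies

Calibration and recovery studies use 2,000 replicates (type-I error,
coverage, Egger calibration), 500 (robust-median, mediation chain), 200
(MR-PRESSO, Steiger), 50 (LDSC), 100 (enrichment ranking); instrument
counts J = 30–50. These sizes give Monte-Carlo SEs comfortably inside the
asserted bands (e.g. ±0.005 on a 5% rejection rate at 2,000 reps) while
keeping the full suite under ten seconds.

## Known limitations

- No multivariable MR, MR-RAPS, contamination mixture, or Bayesian
  estimators; no Radial-MR.
- LD handling is matrix-based; there is no reference-panel computation from
  genotypes, no genomic-window clumping, and no proxy-variant search.
- The LDSC module is a teaching-grade simplification (see above).
- Real-data reproduction of any published screen requires the original
  accession downloads and is out of scope; the package's evidence is
  synthetic parameter recovery.
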