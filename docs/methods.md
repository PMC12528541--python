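# Methods

## Scope and model

`mrmediate` estimates the causal effect of an exposure (a gut microbial
abundance trait) on a binary outcome from two independent GWAS
summary-statistics sources, and decomposes that effect through one
intermediate quantitative trait (a circulating metabolite) by two-step MR.
All effects live on the additive scale — per-allele betas for quantitative
traits, log-odds for the case-control outcome — and odds-ratio output is a
presentation transform, never an internal scale. Readers ingesting
odds-ratio columns log-transform at the boundary (`ColumnMap.effect_is_or`).

The estimand decomposition is the product-of-coefficients rule: total β,
indirect β₁β₂ (exposure→mediator times mediator→outcome), direct β − β₁β₂,
proportion mediated β₁β₂/β. The two identities `direct + indirect = β` and
`proportion·β = indirect` hold by construction (direct and proportion are
defined from β and the indirect product); their floating-point
rearrangements agree to roundoff, which is what the property tests assert.
The proportion is reported even when it is negative or exceeds one, with a
`congruent` flag, because clamping would hide genuine violations of the
single-mediator model.

## Instrument selection

Candidates are SNPs with p below a per-analysis threshold: 5e-8 by
convention, relaxed to 1e-5 for microbiome and metabolite exposures (these
GWAS rarely yield genome-wide-significant hits), and 5e-5 for the reverse
direction with a warning if fewer than 20 instruments result; thresholds
are never auto-relaxed. Greedy clumping accepts the best remaining SNP and
removes neighbours within 10 Mb with r² ≥ 0.001, using a user-supplied
pairwise LD table (absent pairs mean r² = 0). A reference-panel LD
computation is deliberately out of scope at desk scale; the LD table is the
interface where panel-derived values would enter. All orderings tie-break
on (p-value, snp_id) so runs are deterministic.

Per-SNP variance explained is not derivable from summary statistics without
a convention, so two standard forms are offered: 2·eaf·(1−eaf)·β² for a
unit-variance trait when the allele frequency is present, else
t²/(t² + n − 2). Set-level R² is the sum over retained (independent) SNPs,
and instrument strength is F = [R²(n−k−1)]/[k(1−R²)]; sets with F < 10 are
flagged weak and skipped.

## Harmonization

The exposure orientation is canonical; only outcome-side records are
modified. Matching alleles keep the record; swapped alleles negate the
outcome beta and reflect its allele frequency; strand-complemented records
are resolved by complementing the outcome pair first. Palindromic (A/T,
C/G) exposure SNPs are dropped unconditionally — no frequency-based rescue
— and anything else is dropped as incompatible. Missing-in-either-side
SNPs are dropped (no proxy lookup). The action tally always sums to the
snp_id union, and harmonization is idempotent on its own output.

## Estimators and diagnostics

IVW is the primary estimator. Its standard error is multiplicative
random-effects — the fixed-effect se inflated by max(1, √(Q/(J−1))) — which
reduces exactly to fixed-effect under homogeneity; the fixed-effect se is
retained in `extra` for users who prefer it. MR-Egger orients instruments
to non-negative exposure effects, fits weighted least squares with a free
intercept, inflates by max(1, √(Q_egger/(J−2))) and uses t quantiles with
J−2 df for both the slope and the pleiotropy-test intercept (so Egger
confidence bounds use the t critical value where other methods use 1.96).
The weighted median interpolates the sorted ratios across standardized
cumulative weights at 0.5; its se is a parametric bootstrap (default 1000
draws, seed-controlled).

MR-PRESSO measures the observed leave-one-out residual sum
Σ (β_Yj − β̂₍₋ⱼ₎β_Xj)²/σ_Yj² against a parametric null (1000 simulated
replicates by default), with add-one empirical p-values that can never be
exactly zero. Per-SNP outlier p-values are Bonferroni-adjusted across the
J instruments and called at 0.05. The distortion test compares the
estimate shift after outlier removal with shifts from removing equally many
SNPs — exhaustively when there are at most 10,000 subsets, else by random
resampling. The residual weight 1/σ_Yj² on the outcome-beta scale is
algebraically the IVW ratio-scale weight: Σ w_j(r_j − β̂)² with
w_j = β_Xj²/σ_Yj² equals the same sum, which also ties Cochran's Q to the
IVW inflation factor (Q = (J−1)·inflation² whenever inflation > 1).

## Synthetic data generator

The generator emulates the statistical structure of the three sources at
their real scales: exposure GWAS n = 18,340; metabolite GWAS n = 8,299;
binary outcome with 1,316 cases and 313,392 controls entering the standard
errors through the effective sample size 4/(1/n_cases + 1/n_controls) (the
table's `n` column keeps the total count). SNPs are in linkage
equilibrium — the pipeline clumps to independence before estimation, so
estimator inputs are independent by construction and LD handling is
exercised separately through explicit LD-table fixtures. Standard errors
are the exact closed form 1/√(2·MAF(1−MAF)·n) with MAF ~ U(0.1, 0.5);
estimated betas add mean-zero normal noise at that se; p-values are
two-sided normal, clamped at the smallest positive normal double.

Planted structure: exposure SNPs carry γ_j ~ N(0, 0.08²) on the exposure,
θ₁γ_j on the mediator and θ_total·γ_j on the outcome (θ_total is the
*total* effect, so the mediated path is included). Mediator-specific SNPs
carry δ_j ~ N(0, 0.12²) on the mediator, θ₂δ_j on the outcome and nothing
on the exposure — the metabolite's own loci, which is what makes θ₂
identifiable by the mediator→outcome MR, mirroring real data where
metabolites have instruments independent of the microbiome. The effect
spreads were chosen so that roughly half the planted SNPs clear p < 1e-5 at
the stated sample sizes, i.e. ~30 instruments from the default 60 exposure
SNPs — comparable to instrument counts in microbiome MR practice, and large
enough that winner's-curse attenuation of the ratio estimates stays within
a few percent. Defaults plant θ_total = −0.5 with θ₁θ₂ = −0.055
(proportion mediated 0.11).

Horizontal pleiotropy is planted as outcome offsets α_j on a configured
fraction of exposure SNPs. A non-zero pleiotropy *mean* is applied along
sign(γ_j): directional pleiotropy is only meaningful relative to the
exposure-increasing allele (the orientation MR-Egger uses); a constant
offset on arbitrary effect alleles would cancel under orientation and be
undetectable by construction. A configured share of SNPs receives
complementary (palindromic) allele pairs, and a share of outcome records is
written strand-flipped (complemented alleles, unchanged beta) for the
harmonizer to recover.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: LD between instruments, winner's curse
from discovery/replication overlap, allele-frequency differences between
cohorts, population stratification, and non-normal effect-size
distributions. Tests on this generator validate the *machinery* (selection,
harmonization, estimation, diagnostics, decomposition) under the stated
sampling model, not the biological conclusions reachable from any real
dataset.

## Pipeline conventions

The forward scan reports both the uncorrected ("suggestive", p < 0.05) and
Benjamini–Hochberg-corrected tiers; FDR is computed across the whole
exposure family's IVW p-values, the most conservative family choice.
Mediation proceeds on suggestive hits and is flagged `exploratory` in the
report. Mediator screening requires both steps significant at 0.05,
congruent sign of indirect and total effects, and a step-2 odds-ratio CI
whose bounds do not round onto 1.00 at two decimals (the loggable proxy for
"broad CI / marginal significance"); exactly one mediator — the congruent
survivor with the smallest step-2 p — is selected per exposure.
Per-trait seeds derive deterministically from the run seed and the trait's
sorted position, so identical configs give byte-identical reports.

Degenerate inputs: traits with no instrument, an all-weak instrument set,
or no harmonized pairs are recorded as skipped with a reason, never fatal;
estimators needing ≥3 (Egger, weighted median) or ≥4 (MR-PRESSO)
instruments are simply omitted below those counts.

## Problem sizes

The shipped calibration and recovery checks use 200 replicates of 30-SNP
instrument sets (100 replicates for outlier power), sizes at which binomial
/ Monte-Carlo error is well inside the asserted tolerances (±3.5 points on
a 5% rejection rate; ±0.04 on a mean proportion of 0.11) while the whole
suite runs in well under a minute per check.

## Known limitations

- No Steiger directionality filtering and no proxy-SNP lookup.
- Single mediator per exposure; no multivariable-MR decomposition.
- The proportion mediated is reported without a standard error in the main
  tables (a delta-method se would understate uncertainty when β is near
  zero); pathological proportions are flagged, not suppressed.
- LD enters only through user-supplied pairwise tables.
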