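# Methods

## Setting and assumptions

`ivmr` implements two-sample summary-data Mendelian randomization: the
variant–exposure associations come from one GWAS (a continuous exposure
scaled to SD units) and the variant–outcome associations from another
(binary outcome, log-odds scale), with no overlap assumed between samples.
Causal interpretation rests on the usual instrumental-variable conditions —
relevance, independence from confounders, and exclusion restriction — plus,
per estimator, the weaker robustness conditions noted below. Instruments are
treated as independent (LD-pruned); no LD matrix is used anywhere.

Input betas are used on the scale the source declares. The pipeline never
rescales effects silently; per-SD scaling of exposures is the caller's
responsibility, as it is in consortium practice.

## Harmonization

Outcome records are aligned to the exposure's effect allele by exact label
match, label swap (beta negated, frequency complemented), or strand flip
(A↔T/C↔G complement, attempted by default and configurable off). Palindromic
pairs (A/T, C/G) carry no strand information in their labels and are aligned
by frequency concordance instead; they are excluded as ambiguous when either
side's effect-allele frequency falls in the window [0.42, 0.58] (the
conventional two-sample-MR default; configurable) or is missing. Pairs not
reconcilable by swap or complement are excluded as non-concordant. Every
exclusion is logged per variant with an enumerated reason
(`non_concordant`, `palindromic_ambiguous`, `missing_in_outcome`,
`sensitivity_exclusion`), and harmonization is idempotent on already-aligned
data. Non-ambiguous palindromes are kept (frequency-aligned) rather than
dropped wholesale: the exclusion rule targets *ambiguous* palindromes only.

## Estimators

All causal estimates are log odds ratios per SD of exposure; 95% intervals
use the fixed multiplier 1.96, matching forest-plot reporting convention.

- **Wald ratio** (J = 1): β̂_Y/β̂_X with first-order delta SE σ_Y/|β̂_X|.
  The first-order SE ignores exposure-side noise, consistent with standard
  IVW weighting; a `second_order` flag adds the β̂_Y²σ_X²/β̂_X⁴ term.
- **IVW**: computed in regression form (Σ β̂_X β̂_Y/σ_Y² over Σ β̂_X²/σ_Y²),
  which is finite even when an individual β̂_X is zero and is algebraically
  the inverse-variance average of the Wald ratios. Fixed-effects SE
  (Σw)^{-1/2}; the multiplicative-random-effects variant multiplies it by
  max(1, √(Q/(J−1))) — the floor at 1 never deflates SEs. Cochran's Q is
  evaluated in residual form Σ(β̂_Y − θ̂β̂_X)²/σ_Y², chi-square(J−1).
- **Weighted median** (J ≥ 3): order the ratio estimates, normalize the IVW
  weights, place each ratio at cumulative-weight midpoint s_j = Σ_{k≤j}w'_k
  − w'_j/2, and linearly interpolate at s = 0.5. The SE is the standard
  deviation of the estimate over n_boot = 1000 (default, seeded) parametric
  bootstrap draws β̂* ~ N(β̂, σ²) on both sides. Consistent when valid
  instruments carry more than half the weight.
- **MR-Egger** (J ≥ 3): records are first re-oriented so every β̂_X > 0
  (required by the method's derivation; results are invariant to the
  original allele coding). Weighted regression of β̂_Y on β̂_X with free
  intercept, weights σ_Y^{-2}; the intercept estimates the average
  directional pleiotropic effect, the slope the causal effect under InSIDE.
  Standard errors carry the multiplicative overdispersion factor
  max(1, √(RSS_w/(J−2))); inference uses t(J−2). A degenerate design (no
  variation in β̂_X after orientation) raises a collinearity error.

Two-sided p-values come from the normal distribution for Wald, IVW and the
weighted median, and from t(J−2) for both Egger coefficients — matching the
source method literature, which the motivating study follows.

Instrument strength: per-variant F = (β̂_X/σ_X)²; with frequencies and the
exposure sample size available, r²_j = 2·eaf(1−eaf)·β̂_X² and aggregate
F = r²(n−J−1)/((1−r²)J).

## Meta-analysis and multiplicity

Sources (e.g. two outcome consortia) are combined per method with a
fixed-effect inverse-variance meta-analysis — the model is fixed a priori;
between-source Q and I² = max(0,(Q−df)/Q) are reported but never switch the
model. A single source passes through bit-exactly. Benjamini–Hochberg
adjustment (step-up, suffix-minimum form, capped at 1) is applied to the
primary (fixed-effect IVW) combined p-values; the default family is per
outcome across exposures, with a `pooled` option across all outcomes, since
reporting convention groups discoveries per outcome. FDR < 0.05 is labelled
significant; p < 0.05 with FDR ≥ 0.05 suggestive.

## Power

For a binary outcome, the two-sided IVW test's power is approximated by
Φ(|θ|√(n·r²·K(1−K)) − z_{1−α/2}) with n the total outcome sample size and K
the case fraction. The approximation is one-directional: at θ = 0 it returns
α/2 (the rejection mass in one tail), while a literal two-sided test rejects
at rate α — the discrepancy vanishes for any detectable effect. The formula
is cross-validated in the test suite against direct Monte-Carlo simulation
of the full two-sample MR test over a 3×3 grid of (n, θ), agreeing within
two percentage points at 8000 replicates per cell.

## Synthetic-data generator

The generator emulates the two-sample design: J independent Hardy–Weinberg
variants; exposure X = Σa_j g_j + c_x U + e normalized to unit variance,
with one shared confounder U ~ N(0,1) (loadings 0.3/0.3 by default) that MR
must be immune to; outcome via logit P = α₀ + θX + Σγ_j g_j + c_y U, with
the intercept solved numerically so the population prevalence matches its
target before case-control subsampling. Direct effects γ_j are zero,
balanced (zero-mean normal), or directional (constant). Defaults mirror the
motivating study's scale — exposure GWAS n = 8866, outcome GWAS 30,234
cases / 172,122 controls, MAF ~ U(0.1, 0.4), total instrument r² = 0.05
split equally over variants (fatty-acid instruments explain roughly 1–30% of
variance; 5% is mid-range) — with a `reduced()` preset (n = 2000 / 500 /
2000) for fast tests.

Two routes produce identical distributions at matched configurations
(verified by two-sample Kolmogorov–Smirnov on the IVW estimates):
`simulate_individual` simulates genotypes and runs the per-variant OLS and
logistic GWAS regressions (the logistic fits use a small vectorised
Newton/IRLS solver, cross-checked against statsmodels' Logit); and
`simulate_summary` draws β̂_X ~ N(a_j, (n_exp·2maf(1−maf))^{-1/2}) and
β̂_Y ~ N(θa_j + γ_j, (n_eff·2maf(1−maf))^{-1/2}) with
n_eff = n_cases·n_controls/(n_cases+n_controls), orders of magnitude faster
for replicate-heavy calibration. `perturb_alleles` re-encodes outcome
records onto the opposite allele (a consistent recoding harmonization must
undo exactly) and injects palindromic relabellings at a chosen frequency to
exercise the exclusion rules.

What the generator does **not** emulate: LD between instruments, ancestry
structure or stratification, case-control frequency differences beyond the
logistic model, winner's-curse selection of instruments, and sample overlap
beyond a documented flag that reuses exposure-sample individuals in the
outcome population. Passing calibration tests therefore demonstrates
correctness of the estimators under the stated model, not robustness to
those real-data complications.

## Calibration study conditions

Problem sizes were chosen to make Monte-Carlo error small relative to the
tolerances while keeping the default test run light: 1000 random instances
for oracle-equivalence checks (IVW vs weighted least squares through the
origin at 1e-10 relative tolerance; BH vs brute-force suffix minima,
exact); 500 replicates for parameter recovery at θ = ln 1.2, J = 4,
study-scale n (bias bounded by 3 MC SEs, 95% CI coverage required in
[92%, 98%]); 1000 replicates for type-I error at θ = 0 (within 3 MC SEs of
5%). The directional-pleiotropy detection study uses J = 9 with graded
effects a_j = 0.05…0.25 (per-variant effects of real fatty-acid instruments
span an order of magnitude, FADS-dominated) at large samples
(n_exp = 10⁵, 60k/300k outcome), because the Egger intercept is only
identifiable when the β̂_X spread is substantial: a design power analysis
gives intercept SE ≈ 0.006, so a constant γ = 0.03 is detected in ≈99% of
replicates while the slope stays within 3 MC SEs of θ.

## Numerical choices and degenerate inputs

Ties in BH sorting use a stable mergesort (ties are inconsequential for the
adjusted values). Weighted-median interpolation clamps at the extreme
ratios when the target quantile falls outside the midpoint range. A
single-variant instrument collapses IVW to the Wald ratio exactly; zero
exposure effect raises an undefined-ratio error for the Wald ratio while
IVW's regression form remains finite. Empty instruments, insufficient
variant counts (median/Egger need ≥3; the pipeline gates sensitivity
estimators at >4 per reporting convention), and exhausted exclusion lists
raise typed exceptions rather than returning estimates. All stochastic
components (bootstrap, simulators, pipeline) are seeded; pipeline
per-analysis seeds derive from the master seed via `SeedSequence`, making
full runs byte-reproducible.

## Known limitations

First-order ratio SEs ignore exposure-side uncertainty, so CI coverage at
modest instrument strength runs slightly below nominal (observed ~93–95% at
the study scale, within the accepted band) — the standard behaviour of
IVW with estimated weights. No MR-PRESSO, mode-based or multivariable
estimators; no proxy-variant substitution via LD; no correction for sample
overlap (the flag only reproduces the phenomenon). The power approximation
ignores instrument uncertainty and pleiotropy.
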