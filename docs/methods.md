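# Methods

This note documents the models implemented in `repromr`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter when reading results.

## Synthetic cohorts (`repromr.simulate`)

**Genotypes.** Each LD block is a latent Gaussian AR(ρ) process: two
independent haplotype draws per individual are thresholded at the
MAF quantile and summed, so single-SNP genotypes follow Hardy–Weinberg
proportions exactly while neighbouring SNPs correlate through the latent
ρ^|i−j|. Blocks are independent, laid out on chromosomes 1–22 with 1 kb
SNP spacing and 5 Mb between blocks, so a 1 Mb LD-score window spans a
block but never two. MAFs are drawn uniformly on [0.05, 0.5] unless
pinned; a small fraction of SNPs (5% by default) receives strand-ambiguous
A/T or G/C allele pairs so harmonisation and munging paths are exercised.
This gives cheap, tunable LD; it does not attempt recombination-map
realism, MAF–LD coupling, or population structure.

**Traits.** The eight reproductive-factor analogues are generated in
topological order along a directed acyclic graph. A trait is

    direct SNP effects + Σ θ_src·(upstream trait) + γ·C + covariates + noise,

rescaled to unit variance; the per-trait direct-SNP variance is pinned to
the configured h² by empirical scaling. C is a shared heritable confounder
(childhood body-size analogue, h² = 0.2 by default) that loads negatively
on menarche, AFS and AFB. Ever-parous status is a liability-threshold
trait with default prevalence 0.8131 (a never-parous fraction of 18.69%).
Age and a binary batch covariate receive small loadings (0.10 and 0.05) so
covariate adjustment in the scan is non-trivial. Optional missingness is
missing-at-random; informative censoring (e.g. menopause unobserved in
younger women) is not modelled.

**Default effect sizes.** Published MR estimates of reproductive-factor
relationships are *total* effects. Using them directly as DAG edge weights
would both double-count mediated paths and overrun the unit variance
budget (AFB→ALB 0.72 and AFS→ALB 0.42 cannot both be direct alongside
AFS→AFB 0.56). The defaults therefore store **direct** effects obtained by
path subtraction so that the implied totals match the headline estimates,
e.g. direct(AFS→ALB) = 0.42 − 0.56·0.72 ≈ 0.017.
`CausalConfig.total_effect` composes totals for recovery tests. Default
heritabilities (0.05–0.25) are mid-range values for questionnaire-derived
reproductive traits.

**Summary statistics.** `analytic` mode draws `beta_hat ~ N(beta_true, se)`
with `se = 1/√(2·maf·(1−maf)·n)` and unit residual variance (traits are
unit-variance by construction); `individual` mode runs the real per-SNP
regressions. The analytic path is the fast harness for estimator studies;
its SEs agree with the empirical spread of individual-mode scans (tested).

**What passing tests show.** The generator reproduces the statistical
structure the estimators assume — independent instruments after clumping,
Gaussian effect estimates with known SEs, liability-scale binary traits,
configurable overlap — not the biology of real cohorts (no selection bias,
recall error, relatedness or stratification). Recovery results quantify
estimator correctness under those assumptions, not real-data performance.

## Association scans (`repromr.assoc`)

Per-SNP models are OLS (continuous) or logistic (binary; beta = log-odds)
with intercept, age and batch covariates and listwise deletion. The
synthetic cohorts have no relatedness or stratification, so ordinary
regressions take the place a linear mixed model would occupy in a real
biobank-scale scan. The OLS scan is vectorised by residualising trait and
dosages on the covariates once (Frisch–Waugh); the logistic scan is a
vectorised per-SNP Newton solver whose estimates match `statsmodels.Logit`
to 1e-6 (tested). Monomorphic and non-converged SNPs are excluded with a
logged count. p-values are two-sided normal tails of the Wald statistic.

Standardisation to SD units either divides by a known trait SD or uses the
summary-level approximation `beta_sd = z/√(2·eaf·(1−eaf)·(n+z²))`; the two
routes agree within 1% on simulated scans (tested). Whether traits are
standardised before scanning or estimates rescaled after is a user choice;
both routes are exposed and are inverse-consistent.

Instrument selection thresholds at p < 5×10⁻⁸ (strict inequality) and
clumps greedily in ascending p order, ties broken by genomic coordinate
for determinism; r² comes from the supplied reference panel (never from
summary statistics), and the distance window compares positions on the
same chromosome only. The per-SNP variance contribution is
`z²/(z²+n)` — the frequency-form identity `2·eaf·(1−eaf)·beta_sd²` — and
their sum feeds `F = (r²/(1−r²))·((n−k−1)/k)`. That aggregate-r² form
reproduces all eight published worked-example F values within the rounding
of the printed r², which is why it was adopted over the mean of per-SNP F.

## LD score regression (`repromr.ldsc`)

LD scores sum adjusted r² (`r² − (1−r²)/(n_ref−2)`, self term included)
over a 1 Mb window. Munging intersects with the reference SNP list (a
stand-in for HapMap3, exported as a plain SNP-id file so a real list can
be substituted), drops strand-ambiguous SNPs, aligns z signs to the
reference effect allele via swap/complement, and removes chr6:26–34 Mb
(1-based inclusive; extended-MHC long-range LD).

Fits are two-pass weighted least squares: an unweighted pass initialises
(intercept, h²), the second applies `1/(2·(intercept + N·h²·ℓ/M)²) · 1/ℓ`
with h² clamped to [0, 1] and predicted means floored at 0.1 inside the
weights only. This is a documented simplification of the original's
iterative reweighting; recovery tests bound its cost. χ² winsorisation
(`max(80, 0.001·N)` is common practice) is available but off by default —
synthetic z-scores have no data-quality outliers. Standard errors use a
delete-a-block jackknife over position-contiguous blocks (default 200,
at least 10 SNPs per block); **jackknife blocks must span at least one LD
block** to be honest, so the simulation studies pass `n_blocks=50` for a
2,000-SNP panel of 20-SNP LD blocks. The cross-trait regression is
computed symmetrically in the two traits (exact-equality tested); its free
intercept absorbs overlap, with expected value
`n_overlap·pheno_corr/√(N1·N2)` reported alongside for comparison. rg is
reported unclipped; it is undefined (flagged) when either h² estimate is
non-positive.

At a 2,000-SNP reference the regression is intrinsically noisy (per-
realisation SD ≈ 0.1 on h², larger on rg); the acceptance script averages
three independent cohorts for its reported estimate, and single-run checks
use the jackknife SE as the yardstick.

## MR estimators (`repromr.mr`)

**Harmonisation** inner-joins on SNP id, flips swapped outcome alleles
(negating beta, complementing eaf) and resolves strand flips by base
complementation. Palindromic SNPs are first letter-aligned, then retained
only if both allele frequencies are outside 0.5 ± 0.08 and on the same
side; otherwise dropped. The ±0.08 window is a common default — the
convention matters only for the audit trail, which records every action.
Harmonisation is idempotent (tested).

**IVW** is weighted regression through the origin with outcome-precision
weights; the multiplicative random-effects SE is floored at the
fixed-effect SE (`scale ≥ 1`) so heterogeneity can only widen intervals.
**Cochran's Q** uses Wald-ratio weights `se_ratio⁻²`; Q > k−1 flags
heterogeneity. **MR-Egger** re-orients rows to positive exposure betas
(required for identifiability), fits with an intercept, and carries the
same SE floor on k−2 degrees of freedom; `I²_GX` uses exposure-precision
weights `se_exp⁻²` around the weighted mean (the citing literature admits
variants; this is the implemented choice). All normal-theory methods
report `estimate ± 1.96·SE` intervals and two-sided normal p-values.

**SIMEX** perturbs exposure betas with `N(0, λ·se_exp²)` noise at
λ ∈ {0, 0.5, 1, 1.5, 2} (1,000 bootstraps each, closed-form refits), fits
a quadratic in λ to the mean slope and intercept, and extrapolates to
λ = −1; the SE is extrapolated the same way from the per-λ mean SEs. It is
triggered automatically in the pipeline when I²_GX < 0.90. SIMEX trades
bias for variance: it reliably beats the naive slope only when dilution
bias dominates the sampling noise (precise outcome, diluted exposure), the
regime the property test constructs.

**Weighted median** interpolates the sorted ratios at cumulative
standardised weight 0.5 with the midpoint convention `s_i = Σ_{j≤i} w_j −
w_i/2`; **weighted mode** maximises a Gaussian-kernel weighted density
with bandwidth `0.9·min(sd, 1.4826·mad)·k^{−1/5}` (modified Silverman,
factor configurable) on a 512-point grid. Both report parametric-bootstrap
SEs (resampling betas from their sampling distributions), seeded and
deterministic.

Binary-outcome estimates are log-odds per SD of exposure throughout and
exponentiated only at reporting time (`MRResult.odds_ratio()`); mixing
odds-ratio and SD language in one number is a known ambiguity of the
field's reporting, resolved here as OR per SD.

## Sensitivity analyses (`repromr.sensitivity`)

**MR-PRESSO** computes the observed residual sum of squares under
leave-one-out IVW fits, simulates both betas from their sampling
distributions under those fits (1,000 draws by default), and reports the
empirical global p with the `(1+x)/(n+1)` convention. Per-SNP empirical
p-values are Bonferroni-adjusted across instruments — note the resolution
constraint `n_sim > k/α`, otherwise no SNP can be flagged. The corrected
estimate is exactly IVW on the non-outliers; the distortion test compares
the estimate shift against 1,000 random same-size removals. SNPs are
processed in id order so results are invariant to input row order. With
binary outcomes the normal-theory simulation is approximate; results there
are descriptive, not calibrated.

**Steiger** transforms per-SNP t statistics to variance explained
(`r² = t²/(t²+n−2)`; the frequency form `2·eaf·(1−eaf)·beta_sd²` is
available behind a flag but requires SD-unit betas), sums over
instruments, and z-tests the difference of Fisher-transformed
correlations. Filtering drops SNPs whose outcome r² is at least the
exposure r², appending them to the audit list; re-running the estimator on
the filtered set is the caller's responsibility.

**Multivariable IVW** regresses outcome betas on the matrix of exposure
betas (no intercept, outcome-precision weights, all exposures harmonised
to the first one's effect alleles) via `statsmodels.WLS`, with the SE
rescaled to carry the same random-effects floor as univariable IVW — a
single-exposure call reproduces `mr_ivw` exactly (tested). An exposure
whose betas are identically zero is excluded from the design (estimate
undefined) so the remaining exposures reduce to the lower-dimensional
model; any other rank deficiency is an explicit error. Conditional F
statistics and covariance-aware weighting are out of scope.

## Study orchestration (`repromr.pipeline`)

The default temporal order is menarche before everything; AFS before the
childbearing factors, partners and menopause; AFB before ALB, births,
parous and menopause; ALB before menopause. Number of births, parous
status and partners are bidirectional against traits they are not strictly
ordered with; menopause→{menarche, AFS, AFB} are reverse (ovarian-reserve
proxy) analyses; the five negative controls (AFB→menarche, AFS→menarche,
AFB→AFS, menopause→AFS, ALB→menarche) are fixed. The definitive pair list
of a real study lives in its registry; the plan is config-driven and fully
overridable. A pair may appear in more than one category (menopause→AFS is
both reverse and negative control) — duplicates are forbidden within a
category only.

Method minima (IVW 2, Egger/median/mode 3, PRESSO 4 instruments) encode
the fact that sparse instruments preclude sensitivity analysis; pairs with
no instruments are reported as skipped with a reason rather than failing
the bundle. The split-sample workflow scans disjoint random halves, clumps
against the shared full-panel LD reference (per-half LD re-estimation adds
noise without benefit in a homogeneous cohort), runs each pair in both
half-assignments, and pools with a fixed-effects model; when one half
yields no instruments the pair runs once, mirroring sparse exposures such
as ALB or parous status. All multiple-testing reporting is unadjusted; a
Bonferroni column can be derived but is not used for flags.

## Problem sizes

The test suite and acceptance script use: instrument-level studies with
k = 50–150 instruments explaining 6.4% of the exposure and cohorts of
20,000 (200,000 where the published GWAS scale matters for a diagnostic);
LD score regression on a 2,000-SNP, 100-block reference with N = 20,000
(intercept-scaling probes at N = 5,000, where z-products are less
dispersed and the intercept is better identified); cohort-level studies
with 600–1,200 SNPs and 6,000–20,000 individuals. The end-to-end study at
its defaults (20,000 individuals, 1,200 SNPs, full pair plan, LDSC and
split-sample stages) completes in a few minutes on one CPU.

## Known limitations

- Genotypes have no recombination-map realism or population structure;
  clumping and LDSC results on real data will differ quantitatively.
- The LDSC reference is small (thousands of SNPs); estimates carry large
  Monte-Carlo noise relative to genome-wide applications, and the
  jackknife SE is only honest when blocks span the LD correlation length.
- SIMEX SEs are extrapolated rather than jackknifed; treat them as
  approximate.
- MR-PRESSO with binary outcomes, overlap-bias correction (MRlap-style
  estimators) and mediation analysis are out of scope.
- The DAG simulator is a test harness for the estimators, not a claim
  about the true generative mechanism linking reproductive factors.
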