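# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical/design decisions a maintainer would want to
know. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Selection scan

**Model.** Genotype dosages (alt-allele counts, missing mean-imputed) are
standardized per SNP by the binomial scaling √(2p̂(1−p̂)). Population
structure is summarized by the leading K principal components of the
LD-thinned standardized matrix; thinning is a greedy sliding window
(default 200 SNPs) that drops any SNP whose r² with an already-retained
SNP in the window reaches 0.1. Composite r² (squared Pearson correlation
of dosages) is used throughout, so no phasing is needed.

For every SNP — thinned or not — the standardized dosage vector is
regressed on the K score columns (no intercept: both sides are centered).
The coefficient/SE vector **z** is a K-dimensional summary of how strongly
the SNP tracks population structure. Under drift alone, z-rows share a
common scatter; a SNP under recent directional selection in some
population is an outlier. We estimate the center and scatter of the z
cloud robustly — minimum covariance determinant with support fraction
0.75 and an explicit seed (median/MAD² when K = 1) — so that the outliers
we are hunting do not inflate their own null, compute squared Mahalanobis
distances D², rescale by the genomic inflation factor
λ = median(D²)/median(χ²_K), and convert to p_RNS by the χ²_K upper tail.
The full-matrix MCD (rather than componentwise scale estimates) is a
deliberate choice: the z components are correlated whenever drift is
anisotropic across components.

K defaults to 3, appropriate for a continental-scale panel (one axis
separating the most diverged group, two splitting the rest). `k="auto"`
applies a scree-elbow rule — the first component whose variance-explained
drop to its successor falls below 5% of the leading component marks the
noise plateau. With near-equal drift in all populations the structured
eigenvalues are themselves nearly equal, and the rule can undercount;
auto-K is a convenience, the fixed default is the analysis setting.

**Calibration.** The λ correction centers the bulk of the statistic, not
its extreme tail. On neutral two-population simulations the empirical
fraction of p_RNS < 0.05 sits near 0.055 (pooled over replicates); with
four populations and K = 3 the tail is mildly heavier (~0.07), a known
property of the χ² approximation under a drift mixture. Tests therefore
calibrate the scan on the two-population condition and treat marker
definition as a ranking (top-q%) rather than a significance statement,
which is also how the pipeline uses p_RNS downstream.

**F_ST cross-check.** Weir–Cockerham θ̂ (the a/(a+b+c) variance-components
form for two populations of diploids, observed heterozygosity included) is
computed per SNP between two configurable populations. A null is fitted to
the trimmed bulk (default: drop the top and bottom 5%) under
θ̂·df′/mean ~ χ²(df′), by maximizing the *truncated* gamma likelihood —
truncation at the empirical trim bounds is part of the likelihood, which
is what makes df′ recoverable (simulations recover df′ = 5 within ±1 at
n = 10,000). Right-tail p-values follow for all SNPs; negative θ̂ maps to
p ≈ 1. This scan validates PCA outliers: in planted-selection simulations
≥ 70% of the top-100 θ̂ SNPs fall in the scan's top 5%.

## LD clumping, properties, matched sets

Clumping is the standard greedy procedure: repeatedly promote the
unabsorbed SNP with the smallest p (ties broken by genomic order, for
determinism) and absorb unabsorbed SNPs within ±500 kb at r² ≥ 0.1. Both
ranking columns — association p and selection p — are first-class flows,
and an exhaustive brute-force implementation serves as the oracle in
tests.

Matching covariates per SNP: MAF; LD buddies (count of SNPs with r² ≥ 0.5
within ±500 kb); distance to the nearest gene interval (0 inside, ∞ when
no annotation); gene density (intervals overlapping ±100 kb). Matched
null sets draw, per target SNP, uniformly from pool SNPs with MAF within
±0.05 (absolute) and the other three properties within ±50% (relative;
zero targets accept only zero, counts get +1 absolute slack), without
replacement within a set. These tolerances are configurable; the pipeline
widens them stepwise (×1.5 per step, up to 4 steps) when a target has no
candidate, and reports how many widenings were needed.

## Enrichment cascade

Markers are the floor(q·N) LD-independent SNPs with smallest p_RNS
(q = 0.05 by default; boundary ties broken genomically). At each
association threshold the marker × below-threshold 2×2 table is tested by
Fisher's exact test (two-sided p = sum of point probabilities ≤ the
observed one). The reported point estimate is the sample odds ratio
ad/(bc) with the exact conditional CI; a Wald CI on the log odds ratio is
carried alongside, since published enrichment CIs are often Wald-type and
the two can be compared directly.

The partial Spearman correlation rank-transforms −log₁₀ p_GWAS,
−log₁₀ p_RNS and MAF, residualizes the first two on the third, and
correlates the residuals. MAF is the harmonized-panel MAF (the quantity
both statistics actually share). The permutation null permutes the
association ranks against fixed (selection, MAF) pairs and is one-sided in
the enrichment direction with the add-one correction
p = (1+r)/(N+1); a flag switches to the plain ratio r/N for comparison
with software that reports it.

## Derived-allele polarization

The ancestral allele comes from the VCF `AA` tag (first field, parsed
case-insensitively; lowercase calls — the low-confidence alignment
convention — are kept but flagged, with a switch to exclude them). If the
ancestral allele equals the non-effect allele the effect allele is
derived and derived-OR = OR; if it equals the effect allele,
derived-OR = 1/OR; anything else (missing, third allele) is
unpolarizable and reported as such. Direction-bias cells use
log₁₀(derived-OR) — symmetric around 0, so protective and risk effects of
equal strength cancel — with t-based 95% CIs ("no bias" when the CI
covers 0), one-sample t vs 0, Welch two-sample t between marker groups
(group sizes are ~19:1 by construction, so equal variances are not
assumed), and a χ² test on risk-proportion tables with an exact fallback
when any expected count is below 5. Records with derived-OR exactly 1 are
counted separately from protective/risk, since the dichotomy OR<1 / OR>1
leaves them undefined.

## Polygenic scoring

Score = Σ dosage × log(OR) over the chosen SNP set, oriented to the
cohort's counted allele, missing dosages contributing their mean
2·freq·log(OR), standardized to mean 0/SD 1. Explanatory value is the
increment in Nagelkerke's pseudo-R²,
R²_N = [1 − exp((2/n)(ll₀ − ll₁))]/[1 − exp((2/n)·ll₀)] with ll₀ the
intercept-only log-likelihood, between the covariate-only and
covariate+score logistic models — i.e. measured against the covariate
baseline, not the null. Constant covariate columns are dropped (collinear
with the intercept); (quasi-)separation is detected from saturated
fitted probabilities and flagged rather than silently reported.

The covariate-only and intercept-only fits are cached and reused across
the thousands of candidate sets in the matched-null and stratified
analyses; only the full model is refit per set.

Stratified analyses: (i) clumped SNPs with association p < 0.2 are sorted
by p_RNS into 20 contiguous equal-size quantiles (remainder to the last)
and the per-quantile pseudo-R² increment is regressed on quantile rank by
OLS; (ii) the first quantile is compared against matched-set nulls with
empirical p = (1+#{null ≥ target})/(n_sets+1); (iii) four strata
(marker status × derived direction) are resampled — n_draws subsets of
n_snps_per_draw SNPs, without replacement within a draw — and compared by
two-sided Wilcoxon rank-sum. Because draws share SNPs, the resampled R²
values are dependent and the Wilcoxon p-values are anti-conservative;
they are reported as described along with the stratum medians, which are
the robust summary. This caveat is documented rather than "fixed".

Long-range-LD or other exclusion regions only change SNP membership
upstream (at harmonization); no algorithm branches on them.

## Synthetic data

Each population's allele frequency at an LD block is drawn from the
Balding–Nichols law Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) around a shared
ancestral frequency p₀ ~ U(0.05, 0.95); a per-SNP offset shared by all
populations differentiates SNPs within a block without adding
between-population structure. Within an individual, both haploid copies
of a block derive from one latent uniform, which induces strong intra-
block LD (blocks of 5 SNPs by default) for the clumping and LD-buddy
machinery to act on. Selection is modelled as a frequency shift
(±delta_sel, clipped to [0.01, 0.99]) at n_selected loci in one
designated population — the scan statistics used here see only frequency
differentiation, so a sweep haplotype model would add nothing testable.

GWAS summary statistics are drawn as log-odds ~ N(β_true, se²) with
se = 1/√(2p(1−p)·n_eff); a fraction `overlap_frac` of causal loci comes
from the selected set, and at selected-causal loci the derived allele is
protective with probability `pi_prot` (0.5 elsewhere). The target cohort
follows a liability-threshold model: standardized genetic score weighted
by √h², Gaussian environment by √(1−h²), cases above the
prevalence quantile, rejection-sampled in batches; covariates are sex,
age and leading genotype PCs.

Default study conditions: 4 populations × 100 diploids, 20,000 SNPs,
F = 0.1, 100 selected loci with delta 0.3, 200 causal loci with 50%
overlap, β ~ |N(0, 0.08)|, π_prot = 0.8, h² = 0.3, prevalence 1%,
discovery n_eff = 100,000 — continental-scale drift, a strongly powered
discovery GWAS, and a realistically rare disorder. Tests and the
acceptance script run reduced instances (5,000–8,000 SNPs, 50 samples per
population, cohorts of ~500–600, stronger shifts delta = 0.45 with
F = 0.05 for the "strong selection" recovery checks) so the whole suite
completes in minutes; the methods being exercised are size-independent.

What the generator does **not** emulate: realistic demography (admixture,
bottlenecks, migration), recombination-rate variation, long-range LD
beyond block boundaries, imputation error beyond the INFO column, strand
flips, or cross-ancestry effect heterogeneity. Passing recovery tests
therefore demonstrate that the statistics detect planted frequency-shift
selection and direction bias under clean drift — not that any particular
real dataset would show them.

## Numerical choices and edge cases

- Monomorphic SNPs: z-row set to 0, D² = 0, p_RNS = 1 (kept, so joins
  stay aligned); θ̂ undefined (NaN) when monomorphic in both populations.
- Singular robust scatter falls back to its diagonal with a warning.
- Fisher tables with an all-zero margin return p = 1 with the OR flagged
  undefined; enrichment thresholds with no marker below them are flagged
  underpowered, never fatal.
- Harmonization drops allele-mismatched records (counted in the report);
  strand-ambiguous A/T and C/G SNPs are flagged and kept by default (the
  generator never strand-flips; real-data users can enable dropping).
- MAF is min(f, 1−f) of the alt allele on the harmonized panel.
- Seeds: every stochastic stage derives an independent stream from the
  single config seed via labelled SeedSequence children, so stages can be
  re-run in isolation and reproduce the pipeline's numbers exactly.
- Coordinates: VCF/GWAS positions 1-based; BED 0-based half-open.

## Known limitations

- The χ² tail of the scan is approximate in the extreme tail (see
  Calibration above); marker definition is rank-based partly for this
  reason.
- The scree-based auto-K undercounts when population drifts are exactly
  exchangeable; set K explicitly for designed experiments.
- The trimmed-likelihood F_ST null assumes a single shared df′; strong
  hierarchical structure between more than two populations would violate
  it (the scan pair is configurable for exactly this reason).
- Wilcoxon p-values in the direction-stratified resampling are
  anti-conservative by construction (dependent draws); use the medians.
- Matching tolerances are documented approximations of common
  property-matching defaults, exposed as configuration.
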