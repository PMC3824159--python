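# Methods

This note records the statistical model behind `genebin`, the
numerical choices made where several implementations were defensible,
and what the synthetic-data generator does and does not emulate.

## Regression framework

All tests act on one gene region with K biallelic SNPs coded 0/1/2 as
minor-allele counts, and a quantitative trait y for n individuals.

**Joint fit.** Ordinary least squares of y on an intercept plus all K
columns. The slope covariance Σ_B is σ̂²·(X̃ᵀX̃)⁻¹ on centered
columns, with σ̂² the unbiased residual variance (df n − K − 1).
Columns that are collinear *in the sample* are removed by a sequential
Gram–Schmidt rank filter that always keeps the lowest-index member of
a dependent group; the drop is recorded on the fit. This situation
does not arise in dense reference data (two SNPs at r² = 1 land in one
bin) but can arise in finite samples drawn from a haplotype pool. The
tolerance is a relative residual norm of 1e−8.

**Marginal fit.** K simple regressions give β̂ᴹ. The cross-covariance
uses a GEE-type plug-in on centered genotype columns,

    Cov(β̂ᵢᴹ, β̂ⱼᴹ) = σ₀² (x̃ᵢᵀx̃ⱼ) / ((x̃ᵢᵀx̃ᵢ)(x̃ⱼᵀx̃ⱼ)),

with σ₀² the intercept-only (null) trait variance. The diagonal uses
the same formula (i = j) rather than the per-SNP residual variance, so
the matrix is exactly consistent: its correlation equals the genotype
correlation matrix identically, which the test suite asserts to
1e−10. Under the null the two variance choices coincide in
expectation; under alternatives the null-variance version matches the
score-test construction the marginal statistics descend from.

## Test statistics and null distributions

* **Wald** = β̂ᵀΣ_B⁻¹β̂, χ² with K df.
* **MLC** collapses the K effects to L bin-level linear combinations
  with weight matrix W = Σ⁻¹J(JᵀΣ⁻¹J)⁻¹, where J is the K×L bin
  indicator; the statistic simplifies to tᵀ(JᵀΣ⁻¹J)⁻¹t with
  t = JᵀΣ⁻¹v, χ²_L. Flavor B uses (β̂, Σ_B); flavor Z uses the
  standardized statistics and their correlation. J = I recovers Wald
  (asserted to 1e−10); a single all-ones bin recovers the 1-df LC
  test (asserted bit-for-bit).
* **PC80** performs covariance PCA of the centered genotype matrix and
  regresses y on the smallest set of leading components explaining
  strictly more than the variance fraction (default 0.80); the
  quadratic form on those S coefficients is χ²_S. Covariance (not
  correlation) PCA is the default because the selection criterion is
  genotypic variance explained, which is MAF-weighted by construction;
  `standardize=True` switches to correlation PCA.
* **MinP** takes the smallest two-sided per-SNP p-value and adjusts it
  as 1 − P(max|Z| ≤ z*) under MVN(0, R), R the correlation of the
  per-SNP statistics. Two-sided p-values are used because the per-SNP
  statistics are signed and the surrounding framework is χ²-based.
  The rectangle probability is computed by scipy's quasi-Monte-Carlo
  MVN integrator with two independent seeded streams; their mean is
  the estimate and half their difference is reported as the
  integration error. A correlation matrix that fails PSD (numerical
  noise, duplicated columns) is repaired by eigenvalue clipping with
  the perturbation norm recorded.
* **SSB / SSBw** sum squared marginal betas, optionally scaled by
  their variances. The null is Σcᵢχ²₁ with cᵢ the eigenvalues of the
  marginal covariance (SSB) or of its correlation-scaled version
  (SSBw).
* **SKAT** is the weighted score statistic Q = uᵀWu with u = X̃ᵀỹ and
  per-SNP weights the squared Beta(1, 25) density at the MAF. Both y
  and the genotype columns are mean-centered even though the classical
  display writes raw Y'XWX'Y: with an intercept-only null model,
  centering is exactly what makes the stated Σcᵢχ²₁ null (with
  cᵢ = σ₀²·eig(W^{1/2}X̃ᵀX̃W^{1/2})) correct, so the centered form is
  used deliberately.
* **SKAT-C** computes separate components on the low-frequency set
  (Beta(1, 25)² weights) and the common set (Beta(0.5, 0.5)² weights)
  and mixes them as φ·Q_LF + (1 − φ)·Q_common. φ is defined through
  the *null* standard deviation of each component, SD = √(2Σcᵢ²); a
  sampling SD across replicates would be an alternative reading, but
  the null SD is deterministic, replicate-free and available in a
  single-data-set analysis, which is the setting the statistic is used
  in. The combined null spectrum is taken from the stacked half-kernel
  [√φ·X̃_LF W_LF^{1/2} | √(1−φ)·X̃_c W_c^{1/2}], which honors the
  correlation between the two components; for orthogonal blocks it
  reduces to the union of the scaled block spectra (asserted). If one
  variant set is empty the statistic falls back to plain SKAT on the
  other set with φ ∈ {0, 1} recorded.

**Mixture-of-chi-square p-values.** The default route is exact
numerical inversion of the characteristic function (Imhof's formula)
via adaptive quadrature (`scipy.integrate.quad`, absolute tolerance
1e−7); single and equal weight vectors short-circuit to a scaled
chi-square. Liu-type three-moment matching is available as
`method="liu"` — it is an order of magnitude faster but its error can
exceed 0.01 at moderate p-values, which is why it is not the default.
Imhof's integral loses accuracy below p ≈ 1e−5 (oscillatory
cancellation); p-values are clipped to [1e−16, 1] and the package's
operating range is the 0.05 neighborhood. Eigenvalues below
1e−10 × max are treated as zeros; substantially negative eigenvalues
trigger a warning before clipping.

## MAF stratification and binning

SNPs are classified from the *sample* MAF, never from file metadata:
common (MAF ≥ 0.05), low-frequency (0.01 ≤ MAF < 0.05), excluded
(MAF < 0.01, dropped at load time). Boundary values follow the printed
inequalities (0.05 is common, 0.01 is low-frequency). The three
analysis sets — all, common-only, low-frequency-only — are column
subsets; binning and coding correction are run independently within
each set.

Binning is greedy tagging on r² of the genotype columns: among
unassigned SNPs, the one with the most unassigned partners at
r² > threshold (default 0.5, strict) seeds the next bin and absorbs
those partners, so larger bins form first. Ties go to the lowest SNP
index — the choice is arbitrary but fixed, because reproducibility
matters more than which equivalent bin forms first. Binning uses r²
and is therefore invariant to coding flips; the coding correction is
applied *after* binning, within bins only, as one sequential ascending
pass per bin with the bin's correlations updated after each flip
(a flip simply negates the flipped SNP's correlations). A flip occurs
when the count of strictly negative correlations with the other
members exceeds half of them. On every fixture tried a single pass
reaches a fixed point — re-running the correction produces no further
flips — and the suite asserts this.

## Synthetic data generator

The generator stands in for a phased reference panel of a resequenced
gene region. It emulates the features the study design depends on:

* a finite pool of H = 340 haplotypes (mirroring 170 diploid
  founders), diploid genotypes formed by uniform random pairing with
  replacement — hence Hardy–Weinberg genotype variance 2p(1−p), which
  the suite checks;
* 8–15 sites with pool frequency in [0.01, 0.5];
* at least one LD bin containing ≥ 3 low-frequency sites, built from
  lightly perturbed copies of one rare founder pattern (shared
  carriers are what produce high r² between rare variants);
* common sites thresholded from a latent first-order autoregressive
  Gaussian chain (latent correlation drawn in [0.55, 0.8], frequencies
  in [0.10, 0.45]), giving an LD profile that decays along the region;
* mean pairwise |r| constrained to [0.17, 0.59], the range observed
  across real gene panels of this size, with typical accepted values
  near the low end of the band.

Candidate pools are rejection-sampled (cap 500 attempts) until all
constraints hold; pools containing duplicate or complementary site
columns are rejected so that a causal site is never a literal copy of
a tag site. What the generator does **not** emulate: coalescent
genealogy, recombination hotspots, population structure, genotyping
error, or the long allele-frequency tail below 1%. Consequently,
passing tests show the statistics behave as designed under clean
Hardy–Weinberg data with realistic LD summaries — not that they are
robust to confounding or data-quality artifacts.

Five additive trait models are provided, y = a₁C₁ (+ a₂C₂) + ε with
ε ~ N(0, σ²): (1) one low-frequency causal, a₁ = 1; (2) two
deleterious low-frequency causals sharing a bin, (1, 1); (3) two
low-frequency causals sharing a bin with opposing signs, (1, −1);
(4) one common plus one low-frequency causal, (1, 1); (5) one
deleterious common plus one protective low-frequency causal, (1, −1).
Low-frequency causals are drawn from a qualifying bin (≥ 3
low-frequency members); common causals uniformly from all common
sites. Causal columns are excluded from every analysis set — the
causal variants are treated as untyped.

## Power calibration

σ is chosen so the joint-regression Wald test has a target analytic
power (default 0.8 at α = 0.05): the noncentrality is
λ = E[β̂]ᵀ(X̃ᵀX̃)E[β̂] / σ²_resid, with E[β̂] from the
omitted-variable slope formula on the realized genotype sample and
σ²_resid = σ² + Var(signal | X) — the second term is the part of the
causal signal the analysis SNPs cannot capture, typically well under
1% of σ² but included for exactness. Power is strictly decreasing in
σ, so the equation is solved by bracketed root finding on log σ and
the result clamped to [0.0001, 100] with a flag when the target is
unattainable (e.g. zero expected betas). The calibration is validated
two ways: the analytic power curve is monotone on a σ grid, and the
empirical Wald rejection rate at the calibrated σ lands inside the
binomial 99% band around the target over 1000 replicates.

## Study runner and problem sizes

A study fixes a panel, draws genotypes once per trait model (a flag
allows redrawing per replicate), calibrates σ for causal models, and
evaluates the requested statistics on the requested analysis sets over
N replicate trait draws; the empirical type-I error or power is the
rejection proportion at α with an exact binomial CI per cell. Each
replicate's RNG stream is derived from (master seed, model id,
replicate index), so results are independent of evaluation order and
bit-reproducible. The packaged experiments run at n = 2000
individuals and N = 1000 replicates on a 12-SNP panel — large enough
that the asymptotic null laws are accurate and binomial bands are
tight, while a full run stays in the tens of seconds; the full-scale
defaults (n = 5000) are a configuration change, not a code change.

## Known limitations

* Binary traits, covariates, dosage genotypes and mixed models are out
  of scope; the regression contract is intercept + genotypes only.
* Marginal cross-covariance is the null-variance GEE plug-in; a
  per-SNP residual-variance version is not offered.
* MVN rectangle probabilities are quasi-Monte-Carlo estimates
  (integration error ~1e−4, reported per call), so MinP p-values
  carry that noise floor.
* Imhof inversion is unreliable below p ≈ 1e−5; far-tail mixture
  p-values should not be quoted beyond that precision.
* Single-panel studies cannot reproduce across-gene averages or
  across-gene CIs; per-cell CIs here are binomial over replicates.
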