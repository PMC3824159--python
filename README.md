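# genebin

Gene-based multi-marker association testing for quantitative traits,
covering common and low-frequency variants together.

Single-SNP association scans lose power when a gene's effect is spread
over several partially correlated variants, and especially when the
causal variant is untyped and only tagged through linkage
disequilibrium (LD). `genebin` implements a family of *global* gene
tests built from one multiple regression of the trait on all K SNPs in
a gene (`E[Y] = β₀ + β₁X₁ + … + β_K X_K`, additive 0/1/2 minor-allele
coding), or from the K single-SNP marginal regressions, plus the
machinery needed to study them: LD binning, allele-coding correction,
MAF-stratified analysis sets, omitted-causal-variant coefficient
theory, and a seeded simulation engine for type-I error and power.

## Statistics

| statistic | regression | null law | idea |
|---|---|---|---|
| Wald | joint | χ²_K | full quadratic form β̂ᵀΣ_B⁻¹β̂ |
| MLC-B / MLC-Z | joint | χ²_L | linear combination within each of L LD bins, quadratic across bins |
| LC-B / LC-Z | joint | χ²₁ | one covariance-weighted linear combination of all SNPs |
| PC80 | joint | χ²_S | regression on the top genotype PCs explaining >80% variance |
| MinP-J / MinP-M | joint / marginal | MVN max | smallest per-SNP p, adjusted under MVN(0, R) |
| SSB / SSBw | marginal | Σcᵢχ²₁ | (weighted) sum of squared marginal betas |
| SKAT / SKAT-C | marginal score | Σcᵢχ²₁ | Beta(MAF)-weighted kernel score test; SKAT-C mixes rare and common components |

LD bins are built greedily in the LDSelect style (largest bins first)
at r² > 0.5, and within each bin a sequential coding correction flips
a SNP to 2 − g when it is negatively correlated with more than half of
its bin-mates, so the within-bin linear combinations are meaningful.
Mixture-of-chi-square p-values use exact characteristic-function
inversion (Imhof) by default, with Liu-type moment matching as a fast
option.

When causal variants are untyped, the expected coefficient of each
typed SNP follows from omitted-variable theory: regress the causal
genotype C on the typed SNPs to get slopes d, then `E[β̂] = a₁d`
(summed over causal variants), and marginally
`E[β̂ᵢᴹ] = Σ_k a_k ρ_{C_k i} σ_{C_k}/σ_i`. The `expected` module
computes both, and the `simulate` module uses them to calibrate the
trait error SD so the Wald test has a chosen analytic power
(noncentral chi-square inversion, SD clamped to [0.0001, 100]).

## Worked example

```python
import genebin as gb

# synthetic gene panel: 12 SNPs, one LD bin with >=3 low-frequency members
pool = gb.generate_pool(gb.GenePanelSpec(n_snps=12, seed=1))
gm_full = gb.generate_genotypes(pool, 2000, seed=7)
bins_pool = gb.ldselect_bins(pool.correlation_matrix())
tm = gb.assign_causals(pool, bins_pool, model_id=1, seed=15)
gm = gb.analysis_matrix(gm_full, tm)                 # causal SNP left untyped
tm = gb.calibrate_sigma(gm, gm_full, tm, target_power=0.8)

ph = gb.generate_trait(gm_full, tm, seed=3)
gm_corr, bins = gb.build_bins(gm)                    # LD bins + coding correction
jf = gb.fit_joint(gm_corr, ph)
mf = gb.fit_marginals(gm_corr, ph)
for res in (gb.wald(jf), gb.mlc(jf, bins, "B"), gb.lc(jf, "B"),
            gb.minp(jf), gb.ssb(mf), gb.skat(gm_corr, ph)):
    print(f"{res.name:>6}: value = {res.value:10.3f}  p = {res.p_value:.4g}")
```

prints

```
  wald: value =     28.162  p = 0.003057
 mlc-b: value =     26.487  p = 0.0017
  lc-b: value =      0.567  p = 0.4516
minp-j: value =      0.041  p = 0.3511
   ssb: value =      2.555  p = 5.494e-05
  skat: value = 5061784.073  p = 1e-16
```

The trait was generated from one low-frequency causal SNP that is
*excluded* from the analysis set, with noise calibrated so the Wald
test has 80% analytic power. The multi-df joint tests (Wald, MLC-B)
and the marginal quadratic tests (SSB, SKAT) pick up the indirect
association through the causal SNP's LD bin; the 1-df LC test and
MinP, which rely on a single combination or a single best SNP, do not
reach significance on this draw. For MinP the `value` column is the
raw minimum p-value and `p` its multiplicity-adjusted version.

A `genebin` console script exposes the same functionality
(`genebin test`, `genebin bins`, `genebin simulate-panel`,
`genebin calibrate`, `genebin run-study`); see `genebin --help`.

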