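"""Synthetic haplotype pools, genotypes and quantitative traits.

The generator emulates the structure of a resequenced gene region in a
reference panel: a finite pool of phased haplotypes (default 340,
mirroring a panel of 170 diploid founders) over 8-15 biallelic sites
with MAF >= 1%, containing at least one LD bin of three or more
correlated low-frequency SNPs (1% <= MAF < 5%) and a moderate mean
pairwise |r| (accepted band 0.17-0.59 by default).  Diploid genotypes
are formed by randomly pairing haplotypes with replacement, and traits
follow one of five additive causal models with normal error whose SD
is calibrated so the joint-regression Wald test has a target power.

The haplotype model is a latent-threshold construction: common sites
are thresholded from a first-order autoregressive Gaussian chain
(giving a decaying LD profile along the region), and the low-frequency
bin is built from perturbed copies of a rare founder haplotype pattern
(giving the high within-bin r^2 that rare mutual carriers produce).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .binning import BinAssignment, ldselect_bins
from .data import GenotypeMatrix, Phenotype, SnpInfo, classify_maf
from .expected import SIGMA_MAX, SIGMA_MIN, CausalModel, expected_joint_betas

DEFAULT_POOL_SIZE = 340


@dataclass(frozen=True)
class GenePanelSpec:
    """Target structure of a synthetic gene panel.

    ``n_snps`` sites in 8-15; ``lf_bin_min`` low-frequency SNPs
    required to share one LD bin; ``mean_abs_r_band`` the accepted
    range of the mean pairwise |r| across the panel.
    """

    n_snps: int = 12
    lf_bin_min: int = 3
    mean_abs_r_band: tuple[float, float] = (0.17, 0.59)
    n_haplotypes: int = DEFAULT_POOL_SIZE
    r2_threshold: float = 0.5
    seed: int = 0
    max_attempts: int = 500

    def __post_init__(self):
        if not (8 <= self.n_snps <= 15):
            raise ValueError("n_snps must be between 8 and 15")
        if self.lf_bin_min < 2:
            raise ValueError("lf_bin_min must be at least 2")
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even (diploid founders)")
        if self.n_snps < self.lf_bin_min + 2:
            raise ValueError("panel too small for the requested LF bin")


@dataclass
class HaplotypePool:
    """A finite pool of H phased binary haplotypes over K' sites."""

    alleles: np.ndarray
    allele_freqs: np.ndarray
    site_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        H, K = self.alleles.shape
        if H % 2:
            raise ValueError("pool size must be even")
        if self.allele_freqs.size != K:
            raise ValueError("one frequency per site required")
        if np.any(self.allele_freqs < 0.01) or np.any(self.allele_freqs > 0.5):
            raise ValueError("pool site frequencies must lie in [0.01, 0.5]")
        if not self.site_ids:
            self.site_ids = [f"snp{j + 1}" for j in range(K)]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def correlation_matrix(self) -> np.ndarray:
        R = np.corrcoef(self.alleles.astype(float), rowvar=False)
        R = np.atleast_2d(R)
        np.fill_diagonal(R, 1.0)
        return np.clip(R, -1.0, 1.0)

    def freq_classes(self) -> list[str]:
        return [classify_maf(f) for f in self.allele_freqs]

    def mean_abs_r(self) -> float:
        R = self.correlation_matrix()
        iu = np.triu_indices(self.n_sites, k=1)
        return float(np.abs(R[iu]).mean())


@dataclass
class TraitModelSpec:
    """One of the five additive causal trait models.

    1: one low-frequency causal (a1 = 1); 2: two deleterious LF causals
    in the same bin (1, 1); 3: two LF causals in the same bin with
    opposing effects (1, -1); 4: one common and one LF causal, both
    deleterious (1, 1); 5: one deleterious common and one protective LF
    causal (1, -1).  ``error_sd`` stays ``None`` until calibrated.
    """

    model_id: int
    causal_indices: tuple[int, ...]
    effects: tuple[float, ...]
    error_sd: float | None = None
    sigma_clamped: bool = False

    def __post_init__(self):
        if self.model_id not in (1, 2, 3, 4, 5):
            raise ValueError("model_id must be in 1..5")
        if len(self.causal_indices) != len(self.effects):
            raise ValueError("one effect per causal SNP required")


MODEL_EFFECTS: dict[int, tuple[float, ...]] = {
    1: (1.0,),
    2: (1.0, 1.0),
    3: (1.0, -1.0),
    4: (1.0, 1.0),
    5: (1.0, -1.0),
}


def _perturbed_rare_block(
    rng: np.random.Generator, H: int, size: int, base_freq: float
) -> np.ndarray:
    """LF bin sites as lightly perturbed copies of one rare founder
    pattern: shared carriers give high pairwise r^2."""
    n_carriers = max(4, int(round(base_freq * H)))
    base = np.zeros(H, dtype=np.uint8)
    base[rng.choice(H, size=n_carriers, replace=False)] = 1
    cols = []
    for _ in range(size):
        col = base.copy()
        n_flips = rng.integers(0, 2)  # 0 or 1 carrier moved per site
        for _ in range(n_flips):
            carriers = np.flatnonzero(col == 1)
            absent = np.flatnonzero(col == 0)
            col[rng.choice(carriers)] = 0
            col[rng.choice(absent)] = 1
        cols.append(col)
    return np.column_stack(cols)


def _ar1_common_block(
    rng: np.random.Generator, H: int, size: int, phi: float, freqs: np.ndarray
) -> np.ndarray:
    """Common sites thresholded from a latent AR(1) Gaussian chain."""
    z = np.empty((H, size))
    z[:, 0] = rng.standard_normal(H)
    for k in range(1, size):
        z[:, k] = phi * z[:, k - 1] + np.sqrt(1 - phi**2) * rng.standard_normal(H)
    cutoffs = sps.norm.ppf(freqs)
    return (z < cutoffs).astype(np.uint8)


def _has_duplicate_sites(alleles: np.ndarray) -> bool:
    K = alleles.shape[1]
    for i in range(K):
        for j in range(i + 1, K):
            if np.array_equal(alleles[:, i], alleles[:, j]) or np.array_equal(
                alleles[:, i], 1 - alleles[:, j]
            ):
                return True
    return False


def generate_pool(spec: GenePanelSpec) -> HaplotypePool:
    """Draw a haplotype pool satisfying the panel constraints.

    Candidate pools are generated and rejected until the realized panel
    has exactly ``spec.n_snps`` sites with pool frequency >= 1%, at
    least one r^2-bin containing ``spec.lf_bin_min`` or more
    low-frequency sites, and mean pairwise |r| inside the requested
    band.  Raises after ``max_attempts`` with the most common failure.
    """
    rng = np.random.default_rng(spec.seed)
    H = spec.n_haplotypes
    n_lf_block = spec.lf_bin_min + 1
    n_lf_single = 1
    n_common = spec.n_snps - n_lf_block - n_lf_single
    failures = {"maf_filter": 0, "lf_bin": 0, "mean_abs_r": 0, "duplicate_sites": 0}
    for _ in range(spec.max_attempts):
        lf_block = _perturbed_rare_block(
            rng, H, n_lf_block, base_freq=rng.uniform(0.018, 0.042)
        )
        lf_single = (rng.random((H, n_lf_single)) < rng.uniform(0.015, 0.045)).astype(
            np.uint8
        )
        phi = rng.uniform(0.55, 0.8)
        common_freqs = rng.uniform(0.10, 0.45, size=n_common)
        common = _ar1_common_block(rng, H, n_common, phi, common_freqs)
        alleles = np.hstack([common[:, : n_common // 2], lf_block, lf_single,
                             common[:, n_common // 2:]])
        freqs = alleles.mean(axis=0)
        flip = freqs > 0.5
        alleles[:, flip] = 1 - alleles[:, flip]
        freqs = alleles.mean(axis=0)
        keep = freqs >= 0.01
        if keep.sum() != spec.n_snps:
            failures["maf_filter"] += 1
            continue
        kept_alleles = alleles[:, keep]
        # distinct sites required: a causal SNP must never be a literal
        # copy (or complement) of a tag SNP in the pool
        if _has_duplicate_sites(kept_alleles):
            failures["duplicate_sites"] += 1
            continue
        pool = HaplotypePool(kept_alleles, freqs[keep])
        mean_r = pool.mean_abs_r()
        lo, hi = spec.mean_abs_r_band
        if not (lo <= mean_r <= hi):
            failures["mean_abs_r"] += 1
            continue
        bins = ldselect_bins(pool.correlation_matrix(), spec.r2_threshold)
        if not qualifying_lf_bins(pool, bins, spec.lf_bin_min):
            failures["lf_bin"] += 1
            continue
        return pool
    worst = max(failures, key=failures.get)
    raise RuntimeError(
        f"no pool satisfying the panel constraints in {spec.max_attempts} "
        f"attempts (most frequent failure: {worst}, counts {failures})"
    )


def qualifying_lf_bins(
    pool: HaplotypePool, bins: BinAssignment, lf_bin_min: int = 3
) -> list[int]:
    """Bins containing ``lf_bin_min`` or more low-frequency sites."""
    classes = pool.freq_classes()
    out = []
    for b in range(1, bins.n_bins + 1):
        members = bins.members(b)
        if sum(classes[j] == "low_frequency" for j in members) >= lf_bin_min:
            out.append(b)
    return out


def generate_genotypes(
    pool: HaplotypePool, n: int, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Diploid genotypes for n individuals by random pairing of
    haplotypes drawn uniformly with replacement from the pool.

    MAF and frequency class are recomputed from the realized sample.
    Columns monomorphic in the sample are rejected (resample with a
    larger n or a different seed)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.integers(0, pool.n_haplotypes, size=(n, 2))
    G = (pool.alleles[idx[:, 0]] + pool.alleles[idx[:, 1]]).astype(float)
    samples = [f"ind{i + 1}" for i in range(n)]
    infos = []
    for j in range(pool.n_sites):
        freq = G[:, j].mean() / 2.0
        maf = min(freq, 1.0 - freq)
        infos.append(SnpInfo(pool.site_ids[j], j + 1, maf))
    return GenotypeMatrix(samples, infos, G)


def assign_causals(
    pool: HaplotypePool,
    bins: BinAssignment,
    model_id: int,
    seed: int | np.random.Generator = 0,
) -> TraitModelSpec:
    """Select causal site indices for a trait model, uniformly at
    random subject to the model's structural requirements.

    Low-frequency causals come from a bin containing three or more
    low-frequency sites; common causals are drawn from all common
    sites.  Effect signs follow the model definitions.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    effects = MODEL_EFFECTS[model_id]
    classes = pool.freq_classes()
    lf_bins = qualifying_lf_bins(pool, bins)
    if not lf_bins:
        raise ValueError("no bin with 3 or more low-frequency SNPs in this panel")
    b = int(rng.choice(lf_bins))
    lf_members = [j for j in bins.members(b) if classes[j] == "low_frequency"]
    common_sites = [j for j in range(pool.n_sites) if classes[j] == "common"]
    if model_id == 1:
        causals = (int(rng.choice(lf_members)),)
    elif model_id in (2, 3):
        pair = rng.choice(len(lf_members), size=2, replace=False)
        causals = tuple(int(lf_members[i]) for i in pair)
    else:
        if not common_sites:
            raise ValueError("no common SNP available for a common causal")
        causals = (int(rng.choice(common_sites)), int(rng.choice(lf_members)))
    return TraitModelSpec(model_id=model_id, causal_indices=causals, effects=effects)


def generate_trait(
    gm_full: GenotypeMatrix,
    tm: TraitModelSpec,
    seed: int | np.random.Generator,
) -> Phenotype:
    """Quantitative trait Y = a1*C1 (+ a2*C2) + N(0, sigma^2) noise.

    ``gm_full`` must still contain the causal columns; downstream
    analysis should use :func:`analysis_matrix` to exclude them (the
    causal variants are treated as untyped).
    """
    if tm.error_sd is None:
        raise ValueError("trait model has no calibrated error_sd")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = np.zeros(gm_full.n_samples)
    for a, j in zip(tm.effects, tm.causal_indices):
        y = y + a * gm_full.G[:, j]
    y = y + tm.error_sd * rng.standard_normal(gm_full.n_samples)
    return Phenotype(list(gm_full.samples), y)


def analysis_matrix(gm_full: GenotypeMatrix, tm: TraitModelSpec) -> GenotypeMatrix:
    """The genotype matrix handed to the tests: causal columns removed."""
    keep = [j for j in range(gm_full.n_snps) if j not in tm.causal_indices]
    if not keep:
        raise ValueError("removing causal columns leaves no analysis SNPs")
    return gm_full.subset_snps(keep)


def causal_model_from_spec(gm_full: GenotypeMatrix, tm: TraitModelSpec) -> CausalModel:
    C = gm_full.G[:, list(tm.causal_indices)]
    return CausalModel(C, tm.effects, error_sd=tm.error_sd)


def wald_power(sigma: float, lam_unit: float, K: int, alpha: float) -> float:
    """Analytic power of the K-df Wald chi-square test when the
    noncentrality at unit residual variance is ``lam_unit``."""
    crit = sps.chi2.isf(alpha, K)
    return float(sps.ncx2.sf(crit, K, lam_unit / sigma**2))


def calibrate_sigma(
    gm_analysis: GenotypeMatrix,
    gm_full: GenotypeMatrix,
    tm: TraitModelSpec,
    target_power: float = 0.8,
    alpha: float = 0.05,
) -> TraitModelSpec:
    """Choose the trait error SD so the Wald test has the target
    analytic power on this genotype sample.

    The Wald noncentrality is E[beta]' (X'X) E[beta] / residual
    variance, with E[beta] from the omitted-variable slope formula and
    the residual variance including both the noise sigma^2 and the part
    of the causal signal the analysis SNPs cannot capture.  Power is
    strictly decreasing in sigma, so the equation is solved by root
    bracketing; the solution is clamped to [0.0001, 100] (flagged) when
    the target is unattainable in that range.
    """
    cm = CausalModel(
        gm_full.G[:, list(tm.causal_indices)], tm.effects, error_sd=None
    )
    e_beta = expected_joint_betas(gm_analysis, cm)
    Gc = gm_analysis.G - gm_analysis.G.mean(axis=0)
    XtX = Gc.T @ Gc
    num = float(e_beta @ (XtX @ e_beta))
    # residual variance of the causal signal given the analysis SNPs
    signal = cm.causal_genotypes @ np.array(tm.effects)
    fitted = Gc @ np.linalg.solve(XtX, Gc.T @ (signal - signal.mean()))
    v_resid = float(np.mean((signal - signal.mean() - fitted) ** 2))
    K = gm_analysis.n_snps
    if num <= 0:
        tm.error_sd, tm.sigma_clamped = SIGMA_MIN, True
        return tm

    def power_minus_target(log_sigma: float) -> float:
        sigma2 = np.exp(2 * log_sigma)
        lam = num / (sigma2 + v_resid)
        return float(sps.ncx2.sf(sps.chi2.isf(alpha, K), K, lam)) - target_power

    lo, hi = np.log(SIGMA_MIN), np.log(SIGMA_MAX)
    if power_minus_target(hi) > 0:  # even sigma = 100 leaves power above target
        tm.error_sd, tm.sigma_clamped = SIGMA_MAX, True
        return tm
    if power_minus_target(lo) < 0:  # target unreachable even at sigma = 0.0001
        tm.error_sd, tm.sigma_clamped = SIGMA_MIN, True
        return tm
    root = optimize.brentq(power_minus_target, lo, hi, xtol=1e-12)
    tm.error_sd, tm.sigma_clamped = float(np.exp(root)), False
    return tm
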