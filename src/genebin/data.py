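"""Core data containers for gene-based association analysis.

Genotypes are additive minor-allele counts (0/1/2) for a single gene
region; the quantitative phenotype is a plain vector aligned to the same
samples.  SNPs are stratified by minor allele frequency into *common*
(MAF >= 0.05) and *low-frequency* (0.01 <= MAF < 0.05) classes; SNPs
below 1% MAF are excluded from analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

COMMON_MAF_THRESHOLD = 0.05
MIN_MAF = 0.01

FreqClass = Literal["common", "low_frequency", "excluded"]
AnalysisSet = Literal["all", "common", "low_frequency"]


def classify_maf(maf: float) -> FreqClass:
    """Frequency class of a SNP: common (MAF >= 5%), low-frequency
    (1% <= MAF < 5%) or excluded (MAF < 1%).  Boundaries are inclusive
    on the left, matching the MAF strata used throughout."""
    if maf >= COMMON_MAF_THRESHOLD:
        return "common"
    if maf >= MIN_MAF:
        return "low_frequency"
    return "excluded"


@dataclass(frozen=True)
class SnpInfo:
    """Per-SNP metadata. ``maf`` is the sample minor allele frequency
    (always <= 0.5); ``position`` is 1-based as in VCF."""

    id: str
    position: int
    maf: float
    freq_class: FreqClass = field(default="common")

    def __post_init__(self):
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"SNP {self.id}: maf {self.maf} outside [0, 0.5]")
        expected = classify_maf(self.maf)
        if self.freq_class != expected:
            object.__setattr__(self, "freq_class", expected)


class GenotypeMatrix:
    """An n x K additive-coded genotype matrix with per-SNP metadata.

    Parameters
    ----------
    samples
        Sample identifiers, length n.
    snps
        :class:`SnpInfo` records, length K, in column order.
    G
        n x K array with entries in {0, 1, 2} counting minor alleles.

    Monomorphic columns and entries outside {0, 1, 2} are rejected;
    missing genotypes must be resolved (dropped or imputed) before
    construction.
    """

    def __init__(self, samples: Sequence[str], snps: Sequence[SnpInfo], G: np.ndarray):
        G = np.asarray(G, dtype=float)
        if G.ndim != 2:
            raise ValueError("G must be 2-dimensional (samples x SNPs)")
        n, K = G.shape
        if K < 1:
            raise ValueError("at least one SNP required")
        if n < 2:
            raise ValueError("at least two samples required")
        if len(samples) != n:
            raise ValueError(f"{len(samples)} sample ids for {n} genotype rows")
        if len(snps) != K:
            raise ValueError(f"{len(snps)} SNP records for {K} genotype columns")
        if not np.isin(G, (0.0, 1.0, 2.0)).all():
            bad = np.argwhere(~np.isin(G, (0.0, 1.0, 2.0)))[0]
            raise ValueError(
                f"genotype at sample {samples[bad[0]]}, SNP {snps[bad[1]].id} "
                "is not 0/1/2 (missing or dosage data must be resolved first)"
            )
        variances = G.var(axis=0)
        if np.any(variances == 0):
            j = int(np.argmin(variances))
            raise ValueError(f"SNP {snps[j].id} is monomorphic in this sample")
        self.samples = list(samples)
        self.snps = list(snps)
        self.G = G

    @property
    def n_samples(self) -> int:
        return self.G.shape[0]

    @property
    def n_snps(self) -> int:
        return self.G.shape[1]

    @property
    def mafs(self) -> np.ndarray:
        return np.array([s.maf for s in self.snps])

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    @classmethod
    def from_raw(
        cls,
        samples: Sequence[str],
        snp_ids: Sequence[str],
        positions: Sequence[int],
        G: np.ndarray,
        min_maf: float = MIN_MAF,
    ) -> "GenotypeMatrix":
        """Build a matrix from raw allele counts, enforcing the
        minor-allele coding convention.

        Columns whose coded-allele frequency exceeds 0.5 are recoded
        g -> 2 - g so the count is always of the minor allele.
        Monomorphic columns and columns with MAF below ``min_maf`` are
        dropped with a warning.
        """
        G = np.asarray(G, dtype=float)
        keep: list[int] = []
        infos: list[SnpInfo] = []
        G = G.copy()
        for j in range(G.shape[1]):
            freq = G[:, j].mean() / 2.0
            if freq > 0.5:
                G[:, j] = 2.0 - G[:, j]
                freq = 1.0 - freq
            if G[:, j].var() == 0:
                logger.warning("dropping monomorphic SNP %s", snp_ids[j])
                continue
            if freq < min_maf:
                logger.warning(
                    "dropping SNP %s with MAF %.4f < %.2g", snp_ids[j], freq, min_maf
                )
                continue
            keep.append(j)
            infos.append(SnpInfo(str(snp_ids[j]), int(positions[j]), float(freq)))
        if not keep:
            raise ValueError("no SNPs survive the MAF/monomorphism filters")
        return cls(samples, infos, G[:, keep])

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        indices = list(indices)
        return GenotypeMatrix(
            self.samples, [self.snps[j] for j in indices], self.G[:, indices]
        )

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        indices = list(indices)
        return GenotypeMatrix(
            [self.samples[i] for i in indices], self.snps, self.G[indices, :]
        )

    def flip_column(self, j: int) -> None:
        """Recode column j as 2 - g (switch base/risk allele coding).

        The stored MAF is unchanged: it always refers to the minor
        allele, regardless of which allele is currently counted.
        """
        self.G[:, j] = 2.0 - self.G[:, j]

    def __repr__(self) -> str:
        return f"GenotypeMatrix(n={self.n_samples}, K={self.n_snps})"


@dataclass
class Phenotype:
    """A quantitative trait vector aligned to sample ids."""

    samples: list[str]
    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1 or len(self.samples) != self.y.size:
            raise ValueError("phenotype vector must align with sample ids")
        if not np.isfinite(self.y).all():
            raise ValueError("phenotype contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.y.size


def partition_by_maf(gm: GenotypeMatrix, analysis_set: AnalysisSet) -> GenotypeMatrix:
    """Restrict a genotype matrix to one of the three MAF analysis sets.

    ``"all"`` keeps every SNP, ``"common"`` keeps MAF >= 0.05 and
    ``"low_frequency"`` keeps 0.01 <= MAF < 0.05 (both boundaries
    inclusive on the left).  Raises if the requested subset is empty, so
    callers can skip the gene for that analysis set.
    """
    if analysis_set == "all":
        return gm
    if analysis_set not in ("common", "low_frequency"):
        raise ValueError(f"unknown analysis set {analysis_set!r}")
    indices = [j for j, s in enumerate(gm.snps) if s.freq_class == analysis_set]
    if not indices:
        raise ValueError(f"no SNPs in analysis set '{analysis_set}'")
    return gm.subset_snps(indices)


def join_phenotype(gm: GenotypeMatrix, ph: Phenotype) -> tuple[GenotypeMatrix, Phenotype]:
    """Align a genotype matrix and phenotype on their common samples.

    Both objects are restricted to the intersection of sample ids, in
    the genotype matrix's order.  Raises if the intersection is empty.
    """
    pheno_index = {s: i for i, s in enumerate(ph.samples)}
    g_idx = [i for i, s in enumerate(gm.samples) if s in pheno_index]
    if not g_idx:
        raise ValueError("genotype and phenotype samples are disjoint")
    common = [gm.samples[i] for i in g_idx]
    p_idx = [pheno_index[s] for s in common]
    n_dropped = (gm.n_samples - len(common)) + (ph.n_samples - len(common))
    if n_dropped:
        logger.info("join: %d common samples (%d dropped)", len(common), n_dropped)
    return gm.subset_samples(g_idx), Phenotype(common, ph.y[p_idx])
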