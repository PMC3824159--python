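"""LD binning and within-bin allele-coding correction.

SNPs within a gene are clustered into *bins* of mutually correlated
markers using a greedy tagging algorithm in the style of LDSelect
(largest bins first) on the squared Pearson correlation of additive
genotype codes, with r^2 > 0.5 as the default membership threshold.
Because a linear combination of effects within a bin only makes sense
when the members are positively correlated, a sequential coding
correction flips a SNP's 0/1/2 coding (g -> 2 - g) when it is
negatively correlated with more than half of its bin-mates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GenotypeMatrix

DEFAULT_R2_THRESHOLD = 0.5


@dataclass
class BinAssignment:
    """A partition of K SNPs into L bins.

    ``bin_of`` maps SNP index -> bin index in 1..L (no gaps);
    ``flipped`` records which columns had their allele coding switched
    by :func:`coding_correction`.
    """

    n_bins: int
    bin_of: np.ndarray
    flipped: np.ndarray
    threshold: float = DEFAULT_R2_THRESHOLD

    def __post_init__(self):
        self.bin_of = np.asarray(self.bin_of, dtype=int)
        self.flipped = np.asarray(self.flipped, dtype=bool)
        K = self.bin_of.size
        if self.flipped.size != K:
            raise ValueError("bin_of and flipped must have equal length")
        labels = set(self.bin_of.tolist())
        if labels != set(range(1, self.n_bins + 1)):
            raise ValueError(f"bin labels {sorted(labels)} are not 1..{self.n_bins}")

    @property
    def n_snps(self) -> int:
        return self.bin_of.size

    def members(self, b: int) -> np.ndarray:
        return np.flatnonzero(self.bin_of == b)

    def indicator(self) -> np.ndarray:
        """The K x L 0/1 matrix J with J[i, l] = 1 iff SNP i is in bin l+1."""
        J = np.zeros((self.n_snps, self.n_bins))
        J[np.arange(self.n_snps), self.bin_of - 1] = 1.0
        return J

    def subset(self, indices) -> "BinAssignment":
        """Restrict to a subset of SNPs, relabelling bins 1..L' in order
        of first appearance and dropping emptied bins."""
        indices = np.asarray(indices, dtype=int)
        old = self.bin_of[indices]
        relabel: dict[int, int] = {}
        new = np.empty_like(old)
        for i, b in enumerate(old):
            if b not in relabel:
                relabel[b] = len(relabel) + 1
            new[i] = relabel[b]
        return BinAssignment(len(relabel), new, self.flipped[indices], self.threshold)


def correlation_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise Pearson correlation r of the 0/1/2 genotype columns."""
    G = gm.G
    if np.any(G.var(axis=0) == 0):
        raise ValueError("monomorphic column; filter before computing correlations")
    R = np.corrcoef(G, rowvar=False)
    R = np.atleast_2d(R)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def ldselect_bins(R: np.ndarray, threshold: float = DEFAULT_R2_THRESHOLD) -> BinAssignment:
    """Greedy LD binning: repeatedly seed a bin at the unassigned SNP
    tagging the most unassigned partners at r^2 > threshold.

    The seed plus all its above-threshold unassigned partners form the
    next bin, so larger bins are constructed first.  Ties are broken by
    the lowest SNP index.  SNPs with no qualifying partner end up as
    singleton bins.
    """
    R = np.asarray(R, dtype=float)
    K = R.shape[0]
    r2 = R**2
    np.fill_diagonal(r2, 0.0)
    unassigned = np.ones(K, dtype=bool)
    bin_of = np.zeros(K, dtype=int)
    label = 0
    while unassigned.any():
        partners = r2 > threshold
        counts = np.where(unassigned, (partners & unassigned).sum(axis=1), -1)
        seed = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(partners[seed] & unassigned)
        label += 1
        bin_of[seed] = label
        bin_of[members] = label
        unassigned[seed] = False
        unassigned[members] = False
    return BinAssignment(label, bin_of, np.zeros(K, dtype=bool), threshold)


def coding_correction(
    gm: GenotypeMatrix, bins: BinAssignment
) -> tuple[GenotypeMatrix, BinAssignment]:
    """Flip allele coding within bins so correlations are predominantly
    positive.

    Each bin of size >= 2 is scanned once in ascending SNP index; a
    member whose count of strictly negative correlations with the other
    members exceeds half of them is recoded g -> 2 - g, and the bin's
    correlations are updated before the scan continues.  Returns a new
    genotype matrix plus the assignment with flip flags set; the input
    is not modified.
    """
    if bins.n_snps != gm.n_snps:
        raise ValueError("bin assignment does not match the genotype matrix")
    G = gm.G.copy()
    flipped = bins.flipped.copy()
    R = np.corrcoef(G, rowvar=False) if gm.n_snps > 1 else np.ones((1, 1))
    R = np.atleast_2d(R)
    for b in range(1, bins.n_bins + 1):
        members = bins.members(b)
        if members.size < 2:
            continue
        for j in members:
            others = members[members != j]
            n_negative = int(np.sum(R[j, others] < 0))
            if n_negative > others.size / 2.0:
                G[:, j] = 2.0 - G[:, j]
                flipped[j] = ~flipped[j]
                # flipping negates every correlation involving column j
                R[j, :] *= -1.0
                R[:, j] *= -1.0
                R[j, j] = 1.0
    corrected = GenotypeMatrix(gm.samples, gm.snps, G)
    return corrected, BinAssignment(bins.n_bins, bins.bin_of, flipped, bins.threshold)


def build_bins(
    gm: GenotypeMatrix, threshold: float = DEFAULT_R2_THRESHOLD
) -> tuple[GenotypeMatrix, BinAssignment]:
    """Convenience pipeline: correlation -> greedy bins -> coding correction."""
    R = correlation_matrix(gm)
    bins = ldselect_bins(R, threshold)
    return coding_correction(gm, bins)
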