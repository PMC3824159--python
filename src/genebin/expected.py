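"""Expected regression coefficients for typed SNPs when the causal
variants are untyped (omitted-variable theory).

With a trait model Y = a1*C1 (+ a2*C2) + eps and analysis SNPs X that
do not include the causal variants, the joint-regression coefficients
have expectation a1*d (+ a2*f) where d (f) are the least-squares slopes
from regressing the causal genotype on X.  The marginal coefficient of
SNP i has expectation sum_k a_k * rho_{Ck,i} * sigma_{Ck} / sigma_i —
the indirect association transmitted through LD with the causal SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GenotypeMatrix

SIGMA_MIN = 1e-4
SIGMA_MAX = 100.0


@dataclass
class CausalModel:
    """An additive causal trait model Y = a1*C1 (+ a2*C2) + eps.

    ``causal_genotypes`` is n x m (m in {1, 2}) of 0/1/2 codes for the
    untyped causal SNPs; ``effects`` the allelic effect sizes;
    ``error_sd`` the residual SD (``None`` until calibrated).
    """

    causal_genotypes: np.ndarray
    effects: tuple[float, ...]
    error_sd: float | None = None

    def __post_init__(self):
        C = np.atleast_2d(np.asarray(self.causal_genotypes, dtype=float))
        if C.shape[0] == 1 and C.shape[1] > 2:
            C = C.T
        self.causal_genotypes = C
        if C.shape[1] != len(self.effects):
            raise ValueError(
                f"{C.shape[1]} causal columns but {len(self.effects)} effect sizes"
            )
        if not all(np.isfinite(a) for a in self.effects):
            raise ValueError("effect sizes must be finite")
        if self.error_sd is not None and not (
            SIGMA_MIN <= self.error_sd <= SIGMA_MAX
        ):
            raise ValueError(
                f"error_sd {self.error_sd} outside calibration range "
                f"[{SIGMA_MIN}, {SIGMA_MAX}]"
            )


@dataclass
class ExpectedBetas:
    """Expected joint and marginal coefficient vectors plus summaries."""

    joint: np.ndarray
    marginal: np.ndarray


def _check_causals_absent(gm: GenotypeMatrix, cm: CausalModel) -> None:
    for k in range(cm.causal_genotypes.shape[1]):
        c = cm.causal_genotypes[:, k]
        for j in range(gm.n_snps):
            if np.array_equal(c, gm.G[:, j]) or np.array_equal(c, 2.0 - gm.G[:, j]):
                raise ValueError(
                    f"causal variant {k + 1} is identical to analysis SNP "
                    f"{gm.snps[j].id}; the omitted-variable setting requires "
                    "untyped causal variants"
                )


def expected_joint_betas(
    gm: GenotypeMatrix, cm: CausalModel, *, allow_typed: bool = False
) -> np.ndarray:
    """Expected joint-regression coefficients of the typed SNPs.

    Each causal genotype vector is regressed (with intercept) on the
    analysis SNPs; the expected beta vector is the effect-weighted sum
    of those slope vectors.  Raises if a causal column is present in
    the analysis set unless ``allow_typed`` (used only for degenerate
    self-consistency checks).
    """
    if not allow_typed:
        _check_causals_absent(gm, cm)
    Gc = gm.G - gm.G.mean(axis=0)
    XtX = Gc.T @ Gc
    out = np.zeros(gm.n_snps)
    for a, k in zip(cm.effects, range(cm.causal_genotypes.shape[1])):
        c = cm.causal_genotypes[:, k]
        slopes = np.linalg.solve(XtX, Gc.T @ (c - c.mean()))
        out += a * slopes
    return out


def hw_genotype_sd(maf: float) -> float:
    """Genotype SD sqrt(2p(1-p)) under random pairing of haplotypes."""
    return float(np.sqrt(2.0 * maf * (1.0 - maf)))


def expected_marginal_betas(
    gm: GenotypeMatrix,
    cm: CausalModel,
    *,
    use_maf_sd: bool = False,
    allow_typed: bool = False,
) -> np.ndarray:
    """Expected marginal (single-SNP) coefficients of the typed SNPs:
    sum_k a_k * rho_{Ck,i} * sigma_{Ck} / sigma_i.

    By default correlations and SDs are computed from the supplied
    genotype sample; ``use_maf_sd`` replaces the SDs by the
    Hardy-Weinberg form sqrt(2p(1-p)) for design-stage calculations
    where only allele frequencies are known.
    """
    if not allow_typed:
        _check_causals_absent(gm, cm)
    out = np.zeros(gm.n_snps)
    G = gm.G
    if use_maf_sd:
        sigma_i = np.array([hw_genotype_sd(s.maf) for s in gm.snps])
    else:
        sigma_i = G.std(axis=0, ddof=1)
    for a, k in zip(cm.effects, range(cm.causal_genotypes.shape[1])):
        c = cm.causal_genotypes[:, k]
        if use_maf_sd:
            p_c = min(c.mean() / 2.0, 1.0 - c.mean() / 2.0)
            sigma_c = hw_genotype_sd(p_c)
        else:
            sigma_c = c.std(ddof=1)
        if c.std() == 0:
            continue
        rho = np.array(
            [np.corrcoef(c, G[:, j])[0, 1] for j in range(gm.n_snps)]
        )
        out += a * rho * sigma_c / sigma_i
    return out


def summarize_expected_betas(
    eb: ExpectedBetas, threshold: float = 0.5
) -> dict[str, dict[str, float]]:
    """Per-gene summaries of the expected coefficient vectors: fraction
    of |beta| above ``threshold``, sum, absolute sum, mean and absolute
    mean, separately for the joint and marginal vectors."""
    out = {}
    for label, vec in (("joint", eb.joint), ("marginal", eb.marginal)):
        vec = np.asarray(vec, dtype=float)
        out[label] = {
            "frac_abs_gt_threshold": float(np.mean(np.abs(vec) > threshold)),
            "sum": float(vec.sum()),
            "abs_sum": float(np.abs(vec).sum()),
            "mean": float(vec.mean()),
            "abs_mean": float(np.abs(vec).mean()),
        }
    return out


def compute_expected_betas(
    gm: GenotypeMatrix, cm: CausalModel, *, use_maf_sd: bool = False
) -> ExpectedBetas:
    return ExpectedBetas(
        joint=expected_joint_betas(gm, cm),
        marginal=expected_marginal_betas(gm, cm, use_maf_sd=use_maf_sd),
    )
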