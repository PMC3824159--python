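"""Joint and marginal least-squares fits for a gene's SNP set.

The joint fit is an ordinary multiple regression of the trait on all K
SNP columns plus an intercept, yielding beta estimates and their
covariance Sigma_B.  The marginal fit runs K simple regressions and
supplies the cross-covariance of the marginal betas with a GEE-type
plug-in built from centered genotype cross-products and the null
(intercept-only) trait variance; under that construction the
correlation of two marginal betas equals the genotype correlation
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeMatrix, Phenotype

_COLLINEARITY_RTOL = 1e-8


def _cov_to_corr(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class JointFit:
    """Multiple-regression estimates for one gene.

    ``beta``/``cov`` are the slope estimates and their covariance
    Sigma_B (intercept excluded); ``z`` the per-SNP Wald statistics,
    ``corr_z`` their correlation matrix Sigma_Z; ``dropped`` lists the
    original column indices removed for sample collinearity.
    """

    beta: np.ndarray
    cov: np.ndarray
    sigma2: float
    dropped: list[int] = field(default_factory=list)
    kept: list[int] = field(default_factory=list)

    @property
    def z(self) -> np.ndarray:
        return self.beta / np.sqrt(np.diag(self.cov))

    @property
    def corr_z(self) -> np.ndarray:
        return _cov_to_corr(self.cov)

    @property
    def n_snps(self) -> int:
        return self.beta.size


@dataclass
class MarginalFit:
    """Single-SNP regression estimates with GEE-type cross-covariance."""

    beta_m: np.ndarray
    cov_m: np.ndarray
    sigma2: float

    @property
    def z(self) -> np.ndarray:
        return self.beta_m / np.sqrt(np.diag(self.cov_m))

    @property
    def corr_z(self) -> np.ndarray:
        return _cov_to_corr(self.cov_m)

    # aliases mirroring the joint fit so generic statistics accept either
    z_m = z
    corr_zm = corr_z

    @property
    def n_snps(self) -> int:
        return self.beta_m.size


def _select_independent_columns(Gc: np.ndarray) -> tuple[list[int], list[int]]:
    """Greedy rank filter keeping the lowest-index maximal independent
    set of centered columns (deterministic collinearity handling)."""
    n, K = Gc.shape
    kept: list[int] = []
    dropped: list[int] = []
    Q = np.empty((n, 0))
    for j in range(K):
        v = Gc[:, j]
        r = v - Q @ (Q.T @ v)
        if np.linalg.norm(r) <= _COLLINEARITY_RTOL * np.linalg.norm(v):
            dropped.append(j)
            continue
        kept.append(j)
        Q = np.hstack([Q, (r / np.linalg.norm(r))[:, None]])
    return kept, dropped


def fit_joint(gm: GenotypeMatrix, ph: Phenotype) -> JointFit:
    """Fit E[Y] = b0 + b1 X1 + ... + bK XK by ordinary least squares.

    Sigma_B is sigma2_hat * the slope block of (X'X)^-1 with sigma2_hat
    the unbiased residual variance.  Columns that are collinear in the
    sample are dropped deterministically (lowest indices kept) and
    recorded in ``dropped``.
    """
    if gm.n_samples != ph.n_samples:
        raise ValueError("genotypes and phenotype are not aligned; join first")
    y = ph.y
    Gc = gm.G - gm.G.mean(axis=0)
    kept, dropped = _select_independent_columns(Gc)
    if not kept:
        raise ValueError("all genotype columns are collinear with the intercept")
    K = len(kept)
    n = gm.n_samples
    if n <= K + 1:
        raise ValueError(
            f"n = {n} samples cannot support K = {K} SNPs plus intercept; "
            "use a smaller analysis set"
        )
    Xc = Gc[:, kept]
    yc = y - y.mean()
    XtX = Xc.T @ Xc
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by rank filter
        raise ValueError("rank-deficient design after collinearity drops") from exc
    beta = XtX_inv @ (Xc.T @ yc)
    resid = yc - Xc @ beta
    sigma2 = float(resid @ resid) / (n - K - 1)
    cov = sigma2 * XtX_inv
    return JointFit(beta=beta, cov=cov, sigma2=sigma2, dropped=dropped, kept=kept)


def fit_marginals(gm: GenotypeMatrix, ph: Phenotype) -> MarginalFit:
    """Fit the K single-SNP regressions E[Y] = b0j + bj Xj.

    The cross-covariance of the marginal betas is the GEE-type plug-in

        Cov(bi, bj) = sigma0^2 * (xi'xj) / ((xi'xi)(xj'xj))

    on centered genotype columns, with sigma0^2 the intercept-only
    (null) trait variance; the diagonal uses the same formula so the
    matrix is internally consistent and its correlation equals the
    genotype correlation exactly.
    """
    if gm.n_samples != ph.n_samples:
        raise ValueError("genotypes and phenotype are not aligned; join first")
    n = gm.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for marginal fits")
    Gc = gm.G - gm.G.mean(axis=0)
    ss = np.sum(Gc**2, axis=0)
    if np.any(ss == 0):
        raise ValueError("monomorphic column; filter before fitting")
    yc = ph.y - ph.y.mean()
    beta_m = (Gc.T @ yc) / ss
    sigma2 = float(yc @ yc) / (n - 1)
    cov_m = sigma2 * (Gc.T @ Gc) / np.outer(ss, ss)
    return MarginalFit(beta_m=beta_m, cov_m=cov_m, sigma2=sigma2)
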