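"""Global gene-based association statistics and their null distributions.

Twelve statistics are provided, spanning joint-regression tests (Wald,
MLC-B, MLC-Z, LC-B, LC-Z, PC80, MinP-J), marginal-regression tests
(SSB, SSBw, MinP-M), and kernel score tests (SKAT, SKAT-C).  Quadratic
statistics whose null law is a mixture sum c_i * chi2_1 get p-values by
exact characteristic-function inversion (Imhof's method) by default,
with Liu-type moment matching available as a fast approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import integrate
from scipy import stats as sps

from .binning import BinAssignment
from .data import GenotypeMatrix, Phenotype
from .regression import JointFit, MarginalFit

P_FLOOR = 1e-16
_EIG_CLIP_RTOL = 1e-10

STATISTIC_NAMES = (
    "wald",
    "mlc-b",
    "mlc-z",
    "lc-b",
    "lc-z",
    "minp-j",
    "minp-m",
    "pc80",
    "ssb",
    "ssbw",
    "skat",
    "skat-c",
)


@dataclass
class TestResult:
    """One global test outcome: statistic value, null spec and p-value."""

    name: str
    value: float
    p_value: float
    df: int | None = None
    mixture_weights: np.ndarray | None = None
    analysis_set: str = "all"
    n_snps: int | None = None
    n_bins: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"{self.name}: p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# mixture-of-chi-square null


def _clip_weights(weights: np.ndarray) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        raise ValueError("empty weight vector")
    top = weights.max(initial=0.0)
    if top <= 0:
        raise ValueError("all mixture weights are zero or negative")
    low = weights < 0
    if low.any():
        if (weights < -_EIG_CLIP_RTOL * top).any():
            warnings.warn(
                "clipping substantially negative mixture eigenvalues to zero",
                RuntimeWarning,
                stacklevel=3,
            )
        weights = np.where(low, 0.0, weights)
    return weights[weights > 0]


def _imhof_pvalue(q: float, weights: np.ndarray) -> float:
    """Tail probability P(sum c_i A_i > q), A_i ~ chi2_1, by numerical
    inversion of the characteristic function (Imhof's formula)."""

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(weights * u)) - 0.5 * q * u
        rho = np.prod((1.0 + (weights * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(
            integrand, 0.0, np.inf, limit=300, epsabs=1e-7, epsrel=1e-6
        )
    return 0.5 + val / np.pi


def _liu_pvalue(q: float, weights: np.ndarray) -> float:
    """Liu-Tang-Zhang moment matching of the mixture to a (noncentral)
    chi-square surrogate (matches mean, variance and skewness)."""
    c1 = weights.sum()
    c2 = np.sum(weights**2)
    c3 = np.sum(weights**3)
    c4 = np.sum(weights**4)
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2
    t = (q - c1) / np.sqrt(2 * c2)
    x = t * np.sqrt(2 * (dof + 2 * delta)) + dof + delta
    if delta > 0:
        return float(sps.ncx2.sf(x, dof, delta))
    return float(sps.chi2.sf(x, dof))


def mixture_chisq_pvalue(
    q: float,
    weights,
    method: Literal["imhof", "liu"] = "imhof",
) -> float:
    """P-value for a statistic with null law sum_i c_i chi2_1.

    Single or equal weights reduce to a scaled (possibly multi-df)
    chi-square, handled in closed form.  Otherwise ``imhof`` performs
    exact numerical inversion of the characteristic function and
    ``liu`` uses three-moment matching.  Results are clipped to
    [1e-16, 1].
    """
    weights = _clip_weights(np.asarray(weights, dtype=float))
    q = float(q)
    if q <= 0:
        return 1.0
    if weights.size == 1 or np.allclose(weights, weights[0], rtol=1e-12, atol=0.0):
        c = float(weights[0]) if weights.size == 1 else float(weights.mean())
        p = float(sps.chi2.sf(q / c, weights.size))
    elif method == "imhof":
        p = _imhof_pvalue(q, weights)
    elif method == "liu":
        p = _liu_pvalue(q, weights)
    else:
        raise ValueError(f"unknown mixture p-value method {method!r}")
    return float(np.clip(p, P_FLOOR, 1.0))


# ---------------------------------------------------------------------------
# joint-regression quadratic tests


def _quadratic_form(v: np.ndarray, S: np.ndarray) -> float:
    try:
        return float(v @ np.linalg.solve(S, v))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance in quadratic form") from exc


def wald(jf: JointFit, analysis_set: str = "all") -> TestResult:
    """Joint-regression Wald test beta' Sigma_B^-1 beta ~ chi2_K."""
    value = _quadratic_form(jf.beta, jf.cov)
    K = jf.n_snps
    return TestResult(
        name="wald",
        value=value,
        p_value=float(sps.chi2.sf(value, K)),
        df=K,
        analysis_set=analysis_set,
        n_snps=K,
    )


def _mlc_core(v: np.ndarray, S: np.ndarray, J: np.ndarray) -> float:
    """(W'v)' (W'SW)^-1 (W'v) with W = S^-1 J (J'S^-1 J)^-1, which
    simplifies to t' M^-1 t for t = J'S^-1 v and M = J'S^-1 J."""
    Sinv_J = np.linalg.solve(S, J)
    M = J.T @ Sinv_J
    t = Sinv_J.T @ v
    try:
        return float(t @ np.linalg.solve(M, t))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular bin-collapsed covariance J'S^-1J") from exc


def mlc(
    jf: JointFit,
    bins: BinAssignment,
    flavor: Literal["B", "Z"] = "B",
    analysis_set: str = "all",
) -> TestResult:
    """Multi-bin linear combination test (MLC-B on betas with Sigma_B,
    MLC-Z on Z statistics with their correlation), chi2 with L df.

    Within each LD bin the per-SNP effects are combined linearly with
    covariance-derived weights; the bin-level combinations enter a
    quadratic form.  With singleton bins (J = identity) MLC-B equals
    the Wald test; with one all-SNP bin it equals the LC test.
    """
    if bins.n_snps == jf.n_snps + len(jf.dropped) and jf.dropped:
        bins = bins.subset(jf.kept)
    if bins.n_snps != jf.n_snps:
        raise ValueError("bin assignment does not match the fitted SNP set")
    v, S = (jf.beta, jf.cov) if flavor == "B" else (jf.z, jf.corr_z)
    J = bins.indicator()
    value = _mlc_core(v, S, J)
    L = bins.n_bins
    return TestResult(
        name=f"mlc-{flavor.lower()}",
        value=value,
        p_value=float(sps.chi2.sf(value, L)),
        df=L,
        analysis_set=analysis_set,
        n_snps=jf.n_snps,
        n_bins=L,
    )


def lc(jf: JointFit, flavor: Literal["B", "Z"] = "B", analysis_set: str = "all") -> TestResult:
    """Linear combination test: MLC with the single all-ones bin, 1 df."""
    v, S = (jf.beta, jf.cov) if flavor == "B" else (jf.z, jf.corr_z)
    J = np.ones((jf.n_snps, 1))
    value = _mlc_core(v, S, J)
    return TestResult(
        name=f"lc-{flavor.lower()}",
        value=value,
        p_value=float(sps.chi2.sf(value, 1)),
        df=1,
        analysis_set=analysis_set,
        n_snps=jf.n_snps,
        n_bins=1,
    )


def pc80(
    gm: GenotypeMatrix,
    ph: Phenotype,
    variance_fraction: float = 0.80,
    standardize: bool = False,
    analysis_set: str = "all",
) -> TestResult:
    """Principal-component regression test on the smallest set of
    genotype PCs explaining more than ``variance_fraction`` of the
    genotypic variance; Wald-type quadratic form with chi2_S null.

    Covariance PCA (no standardization) is the default so MAF-driven
    variance structure is preserved; ``standardize`` switches to
    correlation PCA.
    """
    if gm.n_samples != ph.n_samples:
        raise ValueError("genotypes and phenotype are not aligned; join first")
    Gc = gm.G - gm.G.mean(axis=0)
    if standardize:
        Gc = Gc / Gc.std(axis=0, ddof=1)
    _, svals, Vt = np.linalg.svd(Gc, full_matrices=False)
    eigvals = svals**2
    frac = np.cumsum(eigvals) / eigvals.sum()
    S = int(np.searchsorted(frac, variance_fraction, side="right")) + 1
    S = min(S, gm.n_snps)
    n = gm.n_samples
    if n <= S + 1:
        raise ValueError(f"n = {n} too small for {S} principal components")
    P = Gc @ Vt[:S].T
    yc = ph.y - ph.y.mean()
    PtP = P.T @ P
    beta = np.linalg.solve(PtP, P.T @ yc)
    resid = yc - P @ beta
    sigma2 = float(resid @ resid) / (n - S - 1)
    value = float(beta @ (PtP @ beta)) / sigma2
    return TestResult(
        name="pc80",
        value=value,
        p_value=float(sps.chi2.sf(value, S)),
        df=S,
        analysis_set=analysis_set,
        n_snps=gm.n_snps,
        extra={"n_components": S},
    )


# ---------------------------------------------------------------------------
# minimum p-value tests


def _nearest_psd(R: np.ndarray) -> tuple[np.ndarray, float]:
    w, V = np.linalg.eigh(R)
    if w.min() >= 0:
        return R, 0.0
    w_clipped = np.clip(w, 0.0, None)
    R2 = (V * w_clipped) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2, float(np.linalg.norm(R2 - R))


def minp(
    fit: JointFit | MarginalFit,
    seed: int = 0,
    analysis_set: str = "all",
) -> TestResult:
    """Minimum-p global test with a multivariate-normal multiple-testing
    adjustment.

    The raw statistic is the smallest two-sided per-SNP p-value; the
    adjusted p-value is 1 - P(max_j |Z_j| <= z*) under MVN(0, R) with R
    the correlation of the per-SNP statistics, evaluated by seeded
    quasi-Monte-Carlo integration.  This accounts for LD-induced
    correlation, unlike a Bonferroni correction.  The QMC integration
    error estimate is reported in ``extra['integration_error']``.
    """
    z = np.asarray(fit.z, dtype=float)
    R = np.asarray(fit.corr_z, dtype=float)
    K = z.size
    p_raw = 2.0 * sps.norm.sf(np.abs(z))
    p_min = float(p_raw.min())
    name = "minp-j" if isinstance(fit, JointFit) else "minp-m"
    if K == 1:
        return TestResult(
            name=name, value=p_min, p_value=p_min, analysis_set=analysis_set, n_snps=1
        )
    R, perturbation = _nearest_psd(R)
    if perturbation > 1e-8:
        warnings.warn(
            f"correlation matrix repaired to nearest PSD (|delta| = {perturbation:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    z_star = float(sps.norm.isf(p_min / 2.0))
    mvn = sps.multivariate_normal(mean=np.zeros(K), cov=R, allow_singular=True)
    upper = np.full(K, z_star)
    lower = -upper
    # two independent QMC streams: their half-difference estimates the error
    probs = [
        float(mvn.cdf(upper, lower_limit=lower, rng=np.random.default_rng(seed + k)))
        for k in (0, 1)
    ]
    inside = float(np.clip(np.mean(probs), 0.0, 1.0))
    p_adj = float(np.clip(1.0 - inside, p_min if p_min < 1 else 0.0, 1.0))
    return TestResult(
        name=name,
        value=p_min,
        p_value=p_adj,
        analysis_set=analysis_set,
        n_snps=K,
        extra={
            "p_raw_min": p_min,
            "integration_error": abs(probs[0] - probs[1]) / 2.0,
            "psd_perturbation": perturbation,
        },
    )


# ---------------------------------------------------------------------------
# marginal sum-of-squares tests


def ssb(
    mf: MarginalFit,
    weighted: bool = False,
    analysis_set: str = "all",
    method: Literal["imhof", "liu"] = "imhof",
) -> TestResult:
    """Sum of squared marginal betas (SSB) or its variance-weighted
    version (SSBw), with a mixture-of-chi-square null.

    SSB = sum_i (beta_i^M)^2 with weights the eigenvalues of the
    marginal covariance Sigma_B^M; SSBw divides each squared beta by
    its variance, so the weights are eigenvalues of the correlation-
    scaled matrix.
    """
    beta = mf.beta_m
    cov = mf.cov_m
    if weighted:
        d = np.diag(cov)
        value = float(np.sum(beta**2 / d))
        scale = 1.0 / np.sqrt(d)
        null_mat = cov * np.outer(scale, scale)
        name = "ssbw"
    else:
        value = float(np.sum(beta**2))
        null_mat = cov
        name = "ssb"
    weights = np.linalg.eigvalsh(null_mat)
    p = mixture_chisq_pvalue(value, weights, method=method)
    return TestResult(
        name=name,
        value=value,
        p_value=p,
        mixture_weights=_clip_weights(weights),
        analysis_set=analysis_set,
        n_snps=beta.size,
    )


# ---------------------------------------------------------------------------
# kernel score tests (SKAT family)


def skat_weights(mafs: np.ndarray, scheme: Literal["lf", "common"] = "lf") -> np.ndarray:
    """Per-SNP kernel weights: squared Beta density at the MAF.

    ``lf`` uses Beta(1, 25), sharply upweighting rare alleles;
    ``common`` uses Beta(0.5, 0.5) for the common-variant component of
    SKAT-C.
    """
    mafs = np.asarray(mafs, dtype=float)
    if scheme == "lf":
        dens = sps.beta.pdf(mafs, 1.0, 25.0)
    elif scheme == "common":
        dens = sps.beta.pdf(mafs, 0.5, 0.5)
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    return dens**2


def _skat_q_and_half_kernel(
    gm: GenotypeMatrix, ph: Phenotype, w: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Return (Q, X_c W^{1/2}, sigma0^2) for a weighted score statistic.

    Both the trait and the genotype columns are mean-centered, which is
    what makes the mixture-of-chi2 null exact for the intercept-only
    null model.
    """
    yc = ph.y - ph.y.mean()
    Gc = gm.G - gm.G.mean(axis=0)
    half = Gc * np.sqrt(w)
    u = half.T @ yc
    q = float(u @ u)
    sigma2 = float(yc @ yc) / (ph.n_samples - 1)
    return q, half, sigma2


def skat(
    gm: GenotypeMatrix,
    ph: Phenotype,
    weight_scheme: Literal["lf", "common"] = "lf",
    analysis_set: str = "all",
    method: Literal["imhof", "liu"] = "imhof",
) -> TestResult:
    """Sequence kernel association test: weighted score statistic
    Q = y' X W X' y with Beta-density MAF weights, mixture-of-chi2 null.

    Computed on centered trait and genotypes; the null mixture weights
    are sigma0^2 times the eigenvalues of W^{1/2} X'X W^{1/2}.
    """
    if gm.n_samples != ph.n_samples:
        raise ValueError("genotypes and phenotype are not aligned; join first")
    w = skat_weights(gm.mafs, weight_scheme)
    q, half, sigma2 = _skat_q_and_half_kernel(gm, ph, w)
    weights = sigma2 * np.linalg.eigvalsh(half.T @ half)
    p = mixture_chisq_pvalue(q, weights, method=method)
    return TestResult(
        name="skat",
        value=q,
        p_value=p,
        mixture_weights=_clip_weights(weights),
        analysis_set=analysis_set,
        n_snps=gm.n_snps,
    )


def skat_c(
    gm_lf: GenotypeMatrix | None,
    gm_common: GenotypeMatrix | None,
    ph: Phenotype,
    analysis_set: str = "all",
    method: Literal["imhof", "liu"] = "imhof",
) -> TestResult:
    """Combined-variant SKAT: phi * Q_LF + (1 - phi) * Q_common.

    The low-frequency component uses Beta(1, 25)^2 weights, the common
    component Beta(0.5, 0.5)^2.  The mixture parameter phi is the ratio
    SD(Q_LF) / (SD(Q_LF) + SD(Q_common)) of the null standard
    deviations sqrt(2 * sum c_i^2).  The combined null spectrum comes
    from the phi-scaled stacked half-kernel, so correlation between the
    two components is honored.  If one variant set is empty the test
    falls back to plain SKAT on the other set.
    """
    if gm_lf is None and gm_common is None:
        raise ValueError("both variant sets are empty")
    if gm_lf is None or gm_common is None:
        only = gm_common if gm_lf is None else gm_lf
        scheme = "common" if gm_lf is None else "lf"
        res = skat(only, ph, weight_scheme=scheme, analysis_set=analysis_set, method=method)
        res.name = "skat-c"
        res.extra["phi"] = 0.0 if gm_lf is None else 1.0
        res.extra["fallback"] = scheme
        return res
    q_lf, half_lf, sigma2 = _skat_q_and_half_kernel(gm_lf, ph, skat_weights(gm_lf.mafs, "lf"))
    q_c, half_c, _ = _skat_q_and_half_kernel(gm_common, ph, skat_weights(gm_common.mafs, "common"))
    ev_lf = sigma2 * np.linalg.eigvalsh(half_lf.T @ half_lf)
    ev_c = sigma2 * np.linalg.eigvalsh(half_c.T @ half_c)
    sd_lf = float(np.sqrt(2.0 * np.sum(np.clip(ev_lf, 0, None) ** 2)))
    sd_c = float(np.sqrt(2.0 * np.sum(np.clip(ev_c, 0, None) ** 2)))
    phi = sd_lf / (sd_lf + sd_c)
    value = phi * q_lf + (1.0 - phi) * q_c
    stacked = np.hstack([np.sqrt(phi) * half_lf, np.sqrt(1.0 - phi) * half_c])
    weights = sigma2 * np.linalg.eigvalsh(stacked.T @ stacked)
    p = mixture_chisq_pvalue(value, weights, method=method)
    return TestResult(
        name="skat-c",
        value=value,
        p_value=p,
        mixture_weights=_clip_weights(weights),
        analysis_set=analysis_set,
        n_snps=gm_lf.n_snps + gm_common.n_snps,
        extra={"phi": phi, "q_lf": q_lf, "q_common": q_c},
    )
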