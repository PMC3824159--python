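"""Global test statistics: identities, null laws and oracles."""

import numpy as np
import pytest
from scipy import stats as sps

import genebin as gb
from genebin.binning import BinAssignment
from genebin.regression import JointFit, fit_joint, fit_marginals
from genebin.stats import mixture_chisq_pvalue, skat_weights

from tests.conftest import random_genotype_matrix


@pytest.fixture(scope="module")
def fits(genotypes, null_phenotype):
    gmc, bins = gb.build_bins(genotypes)
    return gmc, bins, fit_joint(gmc, null_phenotype), fit_marginals(gmc, null_phenotype)


def _identity_bins(K):
    return BinAssignment(K, np.arange(1, K + 1), np.zeros(K, bool))


def _single_bin(K):
    return BinAssignment(1, np.ones(K, int), np.zeros(K, bool))


# ---------------------------------------------------------------------------
# exact structural identities


def test_mlc_b_with_singleton_bins_equals_wald(fits):
    gmc, _, jf, _ = fits
    w = gb.wald(jf)
    m = gb.mlc(jf, _identity_bins(jf.n_snps), "B")
    assert abs(m.value - w.value) < 1e-10
    assert m.df == w.df == jf.n_snps


def test_mlc_with_one_bin_equals_lc_bitwise(fits):
    _, _, jf, _ = fits
    for flavor in ("B", "Z"):
        m = gb.mlc(jf, _single_bin(jf.n_snps), flavor)
        l = gb.lc(jf, flavor)
        assert m.value == l.value
        assert m.p_value == l.p_value
        assert m.df == l.df == 1


def test_pc80_full_rank_equals_wald(genotypes, null_phenotype):
    jf = fit_joint(genotypes, null_phenotype)
    w = gb.wald(jf)
    p = gb.pc80(genotypes, null_phenotype, variance_fraction=1.0)
    assert p.value == pytest.approx(w.value, abs=1e-8)
    assert p.df == genotypes.n_snps


def test_single_snp_reductions(rng):
    gm = random_genotype_matrix(rng, n=200, K=1)
    y = 0.3 * gm.G[:, 0] + rng.standard_normal(200)
    ph = gb.Phenotype(list(gm.samples), y)
    jf = fit_joint(gm, ph)
    mf = fit_marginals(gm, ph)
    z = jf.z[0]
    w = gb.wald(jf)
    assert w.value == pytest.approx(z**2, rel=1e-12)
    assert w.p_value == pytest.approx(2 * sps.norm.sf(abs(z)), rel=1e-6)
    # K = 1: LC and MLC collapse to the Wald statistic
    assert gb.lc(jf, "B").value == pytest.approx(w.value, rel=1e-12)
    # K = 1: MinP adjustment is a no-op
    mp = gb.minp(jf)
    assert mp.p_value == pytest.approx(mp.value, rel=1e-12)
    # K = 1: SSBw is the squared marginal Z with chi2_1 null
    s = gb.ssb(mf, weighted=True)
    assert s.value == pytest.approx(mf.z[0] ** 2, rel=1e-12)
    assert s.p_value == pytest.approx(sps.chi2.sf(s.value, 1), rel=1e-4)


def test_zero_signal_gives_zero_statistic_and_p_one():
    jf = JointFit(beta=np.zeros(3), cov=np.eye(3), sigma2=1.0)
    assert gb.wald(jf).value == 0
    assert gb.wald(jf).p_value == 1.0
    assert gb.lc(jf, "B").value == 0
    assert gb.mlc(jf, _single_bin(3), "B").p_value == 1.0


def test_wald_quadratic_form_closed_case():
    jf = JointFit(beta=np.array([1.0, 0.0]), cov=np.eye(2), sigma2=1.0)
    w = gb.wald(jf)
    assert w.value == pytest.approx(1.0)
    assert w.p_value == pytest.approx(sps.chi2.sf(1.0, 2), rel=1e-12)


def test_lc_vanishes_for_opposed_effects_exchangeable_cov():
    cov = np.array([[1.0, 0.3], [0.3, 1.0]])
    jf = JointFit(beta=np.array([0.7, -0.7]), cov=cov, sigma2=1.0)
    assert gb.lc(jf, "B").value == pytest.approx(0.0, abs=1e-12)


def test_statistics_invariant_under_snp_relabeling(genotypes, null_phenotype):
    perm = np.random.default_rng(5).permutation(genotypes.n_snps)
    gm_p = genotypes.subset_snps(perm)
    jf = fit_joint(genotypes, null_phenotype)
    jf_p = fit_joint(gm_p, null_phenotype)
    assert gb.wald(jf_p).value == pytest.approx(gb.wald(jf).value, rel=1e-9)
    mf = fit_marginals(genotypes, null_phenotype)
    mf_p = fit_marginals(gm_p, null_phenotype)
    assert gb.ssb(mf_p).value == pytest.approx(gb.ssb(mf).value, rel=1e-9)
    assert gb.skat(gm_p, null_phenotype).value == pytest.approx(
        gb.skat(genotypes, null_phenotype).value, rel=1e-9
    )


def test_wald_invariant_under_coding_flip(genotypes, null_phenotype):
    flipped = genotypes.subset_snps(range(genotypes.n_snps))
    flipped.flip_column(0)
    flipped.flip_column(5)
    w1 = gb.wald(fit_joint(genotypes, null_phenotype))
    w2 = gb.wald(fit_joint(flipped, null_phenotype))
    assert w2.value == pytest.approx(w1.value, rel=1e-9)


# ---------------------------------------------------------------------------
# mixture-of-chi-square machinery


def test_mixture_single_weight_is_scaled_chisq():
    assert mixture_chisq_pvalue(3.0, [1.5]) == pytest.approx(sps.chi2.sf(2.0, 1), rel=1e-10)


def test_mixture_equal_weights_is_multi_df_chisq():
    assert mixture_chisq_pvalue(6.0, [2.0, 2.0, 2.0]) == pytest.approx(
        sps.chi2.sf(3.0, 3), rel=1e-10
    )


def test_mixture_rejects_degenerate_weights():
    with pytest.raises(ValueError):
        mixture_chisq_pvalue(1.0, [0.0, 0.0])
    with pytest.raises(ValueError):
        mixture_chisq_pvalue(1.0, [])


@pytest.mark.parametrize(
    "weights,q",
    [
        ((2.0, 1.0), 3.0),
        ((5.0, 1.0, 0.5), 4.0),
        ((0.5, 0.3, 0.2, 0.1), 2.2),
        ((10.0, 1.0), 12.0),
        ((1.0, 0.9, 0.5, 0.2, 0.1, 0.05), 3.0),
    ],
)
def test_mixture_pvalue_matches_monte_carlo(weights, q):
    """Exact inversion agrees with a 10^6-draw Monte-Carlo tail."""
    rng = np.random.default_rng(hash(weights) % 2**31)
    draws = rng.chisquare(1, size=(10**6, len(weights))) @ np.array(weights)
    mc = float((draws > q).mean())
    assert mixture_chisq_pvalue(q, weights, method="imhof") == pytest.approx(mc, abs=0.005)


def test_liu_approximation_close_at_operating_level():
    # moment matching is meant for the 0.05 neighborhood
    weights = (0.5, 0.3, 0.2, 0.1)
    q = 2.2  # p near 0.1
    exact = mixture_chisq_pvalue(q, weights, method="imhof")
    liu = mixture_chisq_pvalue(q, weights, method="liu")
    assert liu == pytest.approx(exact, abs=0.01)


# ---------------------------------------------------------------------------
# MinP


def test_minp_independent_z_matches_sidak():
    rng = np.random.default_rng(8)
    K = 6
    z = rng.standard_normal(K)
    jf = JointFit(beta=z, cov=np.eye(K), sigma2=1.0)
    res = gb.minp(jf, seed=3)
    p_min = 2 * sps.norm.sf(np.abs(z)).min()
    sidak = 1 - (1 - p_min) ** K
    assert res.p_value == pytest.approx(sidak, abs=5e-3)


def test_minp_perfectly_correlated_equals_raw(rng):
    x = rng.binomial(2, 0.3, 400).astype(float)
    gm = gb.GenotypeMatrix(
        [f"i{k}" for k in range(400)],
        [gb.SnpInfo("a", 1, 0.3), gb.SnpInfo("b", 2, 0.3)],
        np.column_stack([x, x]),
    )
    mf = fit_marginals(gm, gb.Phenotype(list(gm.samples), rng.standard_normal(400)))
    res = gb.minp(mf, seed=1)
    assert res.p_value == pytest.approx(res.value, abs=5e-3)


def test_minp_adjusted_at_least_raw(fits):
    _, _, jf, mf = fits
    for fit in (jf, mf):
        res = gb.minp(fit, seed=0)
        assert res.p_value >= res.value - 1e-12
        assert res.extra["integration_error"] < 1e-3


# ---------------------------------------------------------------------------
# SKAT family


def test_skat_weights_upweight_rare():
    w = skat_weights(np.array([0.01, 0.05, 0.2, 0.5]), "lf")
    assert np.all(np.diff(w) < 0)  # strictly decreasing in MAF
    assert skat_weights(np.array([1e-9]), "lf")[0] == pytest.approx(625.0, rel=1e-6)


def test_skat_single_snp_matches_marginal_score_test(rng):
    gm = random_genotype_matrix(rng, n=1000, K=1)
    y = rng.standard_normal(1000)
    ph = gb.Phenotype(list(gm.samples), y)
    res = gb.skat(gm, ph)
    # one eigenvalue: Q / (sigma2 * x'x) ~ chi2_1
    yc = y - y.mean()
    xc = gm.G[:, 0] - gm.G[:, 0].mean()
    w = skat_weights(gm.mafs, "lf")[0]
    q_norm = res.value / (res.mixture_weights[0])
    assert res.p_value == pytest.approx(sps.chi2.sf(q_norm, 1), rel=1e-6)
    # agrees with the marginal score test z^2 = (x'y)^2 / (sigma2 x'x)
    z2 = (xc @ yc) ** 2 / ((yc @ yc) / (999) * (xc @ xc))
    assert q_norm == pytest.approx(z2, rel=1e-12)


def test_skat_c_combines_components_with_phi(genotypes, null_phenotype):
    lf_idx = [j for j, s in enumerate(genotypes.snps) if s.freq_class == "low_frequency"]
    c_idx = [j for j, s in enumerate(genotypes.snps) if s.freq_class == "common"]
    lf = genotypes.subset_snps(lf_idx)
    co = genotypes.subset_snps(c_idx)
    res = gb.skat_c(lf, co, null_phenotype)
    assert 0 < res.extra["phi"] < 1
    assert res.value == pytest.approx(
        res.extra["phi"] * res.extra["q_lf"] + (1 - res.extra["phi"]) * res.extra["q_common"],
        rel=1e-12,
    )


def test_skat_c_falls_back_without_lf_set(genotypes, null_phenotype):
    c_idx = [j for j, s in enumerate(genotypes.snps) if s.freq_class == "common"]
    co = genotypes.subset_snps(c_idx)
    res = gb.skat_c(None, co, null_phenotype)
    ref = gb.skat(co, null_phenotype, weight_scheme="common")
    assert res.extra["phi"] == 0.0
    assert res.value == pytest.approx(ref.value, rel=1e-12)
    assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)


def test_skat_c_orthogonal_blocks_union_spectrum(rng):
    """With mutually orthogonal variant blocks the combined null
    spectrum is the union of the phi- and (1-phi)-scaled block spectra."""
    patterns = np.array(
        [
            [0, 0, 0, 0, 2, 2, 2, 2],
            [0, 0, 2, 2, 0, 0, 2, 2],
            [0, 2, 0, 2, 0, 2, 0, 2],
        ],
        dtype=float,
    ).T
    G = np.vstack([patterns] * 10)
    n = G.shape[0]
    samples = [f"i{k}" for k in range(n)]
    # kernel weights come from the recorded MAFs; pick values that keep
    # both blocks on a comparable scale
    infos = [gb.SnpInfo("a1", 1, 0.03), gb.SnpInfo("a2", 2, 0.04), gb.SnpInfo("b1", 3, 0.3)]
    gm_a = gb.GenotypeMatrix(samples, infos[:2], G[:, :2])
    gm_b = gb.GenotypeMatrix(samples, infos[2:], G[:, 2:])
    ph = gb.Phenotype(samples, rng.standard_normal(n))
    res = gb.skat_c(gm_a, gm_b, ph)
    phi = res.extra["phi"]
    s2 = np.var(ph.y, ddof=1)
    Gc = G - G.mean(axis=0)
    w_a = skat_weights(gm_a.mafs, "lf")
    w_b = skat_weights(gm_b.mafs, "common")
    block_a = phi * s2 * np.linalg.eigvalsh((Gc[:, :2] * np.sqrt(w_a)).T @ (Gc[:, :2] * np.sqrt(w_a)))
    block_b = (1 - phi) * s2 * np.linalg.eigvalsh((Gc[:, 2:] * np.sqrt(w_b)).T @ (Gc[:, 2:] * np.sqrt(w_b)))
    expected = np.sort(np.concatenate([block_a, block_b]))
    np.testing.assert_allclose(np.sort(res.mixture_weights), expected[expected > 1e-12], rtol=1e-8)
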