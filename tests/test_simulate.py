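"""Haplotype-pool generator, genotype sampling, trait models and the
power calibration."""

import numpy as np
import pytest
from scipy import stats as sps

import genebin as gb
from genebin.simulate import (
    GenePanelSpec,
    MODEL_EFFECTS,
    calibrate_sigma,
    qualifying_lf_bins,
)


def test_same_seed_gives_identical_pool():
    a = gb.generate_pool(GenePanelSpec(seed=13))
    b = gb.generate_pool(GenePanelSpec(seed=13))
    np.testing.assert_array_equal(a.alleles, b.alleles)
    c = gb.generate_pool(GenePanelSpec(seed=14))
    assert not np.array_equal(a.alleles, c.alleles)


def test_pool_satisfies_structural_constraints(pool):
    spec = GenePanelSpec(n_snps=12, seed=1)
    assert pool.n_sites == 12
    assert pool.n_haplotypes == 340
    assert np.all(pool.allele_freqs >= 0.01) and np.all(pool.allele_freqs <= 0.5)
    lo, hi = spec.mean_abs_r_band
    assert lo <= pool.mean_abs_r() <= hi
    bins = gb.ldselect_bins(pool.correlation_matrix(), spec.r2_threshold)
    assert qualifying_lf_bins(pool, bins, spec.lf_bin_min)
    classes = pool.freq_classes()
    assert "low_frequency" in classes and "common" in classes
    # low-frequency sites really are in [0.01, 0.05)
    for f, c in zip(pool.allele_freqs, classes):
        if c == "low_frequency":
            assert 0.01 <= f < 0.05
        else:
            assert 0.05 <= f <= 0.5


@pytest.mark.parametrize("bad", [dict(n_snps=7), dict(n_snps=16), dict(n_haplotypes=341)])
def test_panel_spec_validation(bad):
    with pytest.raises(ValueError):
        GenePanelSpec(**bad)


def test_genotypes_are_haplotype_sums(pool):
    gm = gb.generate_genotypes(pool, 200, seed=3)
    assert gm.G.shape == (200, pool.n_sites)
    assert np.isin(gm.G, (0, 1, 2)).all()
    # determinism
    gm2 = gb.generate_genotypes(pool, 200, seed=3)
    np.testing.assert_array_equal(gm.G, gm2.G)


def test_sample_maf_tracks_pool_frequency(pool):
    n = 4000
    gm = gb.generate_genotypes(pool, n, seed=9)
    sample_freq = gm.G.mean(axis=0) / 2
    se = np.sqrt(pool.allele_freqs * (1 - pool.allele_freqs) / (2 * n))
    assert np.all(np.abs(sample_freq - pool.allele_freqs) < 4 * se + 1e-9)


def test_hardy_weinberg_genotype_variance(pool):
    gm = gb.generate_genotypes(pool, 4000, seed=10)
    p = gm.G.mean(axis=0) / 2
    expected_var = 2 * p * (1 - p)
    observed = gm.G.var(axis=0)
    assert np.all(np.abs(observed / expected_var - 1) < 0.12)


@pytest.mark.parametrize("model_id", [1, 2, 3, 4, 5])
def test_assign_causals_respects_model_structure(pool, model_id):
    bins = gb.ldselect_bins(pool.correlation_matrix())
    classes = pool.freq_classes()
    tm = gb.assign_causals(pool, bins, model_id, seed=31)
    assert tm.effects == MODEL_EFFECTS[model_id]
    if model_id == 1:
        (c1,) = tm.causal_indices
        assert classes[c1] == "low_frequency"
    elif model_id in (2, 3):
        c1, c2 = tm.causal_indices
        assert c1 != c2
        assert classes[c1] == classes[c2] == "low_frequency"
        assert bins.bin_of[c1] == bins.bin_of[c2]
    else:
        c1, c2 = tm.causal_indices
        assert classes[c1] == "common" and classes[c2] == "low_frequency"


def test_trait_is_causal_combination_plus_noise(pool):
    gm = gb.generate_genotypes(pool, 300, seed=4)
    bins = gb.ldselect_bins(pool.correlation_matrix())
    tm = gb.assign_causals(pool, bins, 1, seed=2)
    tm.error_sd = 1e-4  # effectively noiseless
    ph = gb.generate_trait(gm, tm, seed=6)
    np.testing.assert_allclose(ph.y, gm.G[:, tm.causal_indices[0]], atol=1e-3)
    # null effects -> pure noise with the requested variance
    tm0 = gb.TraitModelSpec(1, tm.causal_indices, (0.0,), error_sd=2.0)
    ph0 = gb.generate_trait(gm, tm0, seed=6)
    assert ph0.y.std() == pytest.approx(2.0, rel=0.2)


def test_trait_requires_calibrated_sigma(pool):
    gm = gb.generate_genotypes(pool, 50, seed=4)
    tm = gb.TraitModelSpec(1, (0,), (1.0,))
    with pytest.raises(ValueError, match="error_sd"):
        gb.generate_trait(gm, tm, seed=0)


def test_analysis_matrix_excludes_causals(pool):
    gm = gb.generate_genotypes(pool, 200, seed=8)
    tm = gb.TraitModelSpec(2, (3, 4), (1.0, 1.0))
    gm_a = gb.analysis_matrix(gm, tm)
    assert gm_a.n_snps == gm.n_snps - 2
    removed = {gm.snps[3].id, gm.snps[4].id}
    assert removed.isdisjoint(gm_a.snp_ids)


@pytest.fixture(scope="module")
def calibration_setup(pool):
    gm_full = gb.generate_genotypes(pool, 2000, seed=7)
    bins = gb.ldselect_bins(pool.correlation_matrix())
    tm = gb.assign_causals(pool, bins, 1, seed=3)
    gm_a = gb.analysis_matrix(gm_full, tm)
    return gm_full, gm_a, tm


class TestCalibration:
    def test_analytic_power_decreasing_in_sigma(self, calibration_setup):
        from genebin.expected import CausalModel, expected_joint_betas

        gm_full, gm_a, tm = calibration_setup
        cm = CausalModel(gm_full.G[:, list(tm.causal_indices)], tm.effects)
        e_beta = expected_joint_betas(gm_a, cm)
        Gc = gm_a.G - gm_a.G.mean(axis=0)
        num = float(e_beta @ (Gc.T @ Gc @ e_beta))
        K = gm_a.n_snps
        crit = sps.chi2.isf(0.05, K)
        powers = [float(sps.ncx2.sf(crit, K, num / s**2)) for s in (0.5, 1, 2, 4, 8)]
        assert all(a > b for a, b in zip(powers, powers[1:]))

    def test_calibrated_sigma_hits_target(self, calibration_setup):
        gm_full, gm_a, tm = calibration_setup
        tm = calibrate_sigma(gm_a, gm_full, tm, target_power=0.8)
        assert not tm.sigma_clamped
        assert 1e-4 < tm.error_sd < 100

    def test_clamping_flags(self, calibration_setup):
        gm_full, gm_a, tm = calibration_setup
        # an enormous effect cannot be brought down to 80% power by
        # sigma <= 100 -> clamped high
        big = gb.TraitModelSpec(tm.model_id, tm.causal_indices, (4000.0,))
        big = calibrate_sigma(gm_a, gm_full, big, target_power=0.8)
        assert big.sigma_clamped and big.error_sd == 100.0
        # zero effect -> no signal -> clamped low with target unattainable
        null = gb.TraitModelSpec(tm.model_id, tm.causal_indices, (0.0,))
        null = calibrate_sigma(gm_a, gm_full, null, target_power=0.8)
        assert null.sigma_clamped and null.error_sd == pytest.approx(1e-4)

    def test_empirical_power_matches_analytic_target(self, calibration_setup):
        """Simulation oracle: the Wald rejection rate at the calibrated
        sigma is close to the 0.8 design target."""
        gm_full, gm_a, tm = calibration_setup
        tm = calibrate_sigma(gm_a, gm_full, tm, target_power=0.8)
        rng = np.random.default_rng(77)
        rej = 0
        n_rep = 400
        for _ in range(n_rep):
            ph = gb.generate_trait(gm_full, tm, rng)
            if gb.wald(gb.fit_joint(gm_a, ph)).p_value < 0.05:
                rej += 1
        rate = rej / n_rep
        assert abs(rate - 0.8) < 3.5 * np.sqrt(0.8 * 0.2 / n_rep)


def test_pool_failure_reports_dominant_constraint():
    # an impossible LD band cannot be satisfied
    spec = GenePanelSpec(seed=0, mean_abs_r_band=(0.99, 1.0), max_attempts=20)
    with pytest.raises(RuntimeError, match="mean_abs_r"):
        gb.generate_pool(spec)
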