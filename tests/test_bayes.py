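"""Gibbs samplers: determinism, shrinkage, model relationships."""

import numpy as np
import pytest

import gpcomp as gp
from gpcomp.bayes import McmcConfig, batch_means_mcse, gebv_from_effects, run_mcmc

from conftest import make_geno


@pytest.fixture(scope="module")
def qtl_data():
    """Small training set with one planted large-effect QTL."""
    cfg = gp.desk_scale_config(
        seed=21, n_founders=150, n_generations=1, offspring_per_mating=2,
        n_markers=200, architecture="sparse", n_qtl=1, target_h2=0.5,
        fixed_effect_spec=(),
    )
    ped, geno, truth, pheno = gp.simulate_dataset(cfg)
    return geno, truth, pheno["trait"].to_numpy()


class TestConfig:
    def test_burn_in_bounds(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcConfig(model="BayesX")
        with pytest.raises(ValueError):
            McmcConfig(pi_zero=1.5)


class TestChainBehaviour:
    def test_deterministic_under_seed(self, qtl_data):
        geno, truth, y = qtl_data
        cfg = McmcConfig(model="BayesC", n_iter=400, burn_in=100, seed=5)
        a = run_mcmc(geno, y, cfg)
        b = run_mcmc(geno, y, cfg)
        assert np.array_equal(a.effect_mean, b.effect_mean)
        assert np.array_equal(a.sigma_e2_trace, b.sigma_e2_trace)

    def test_null_phenotype_shrinks_effects(self):
        # phenotypes independent of genotypes: GEBVs carry no signal, and
        # the largest posterior-mean effect shrinks as n grows
        max_eff = {}
        for nf in (150, 600):
            cfg = gp.desk_scale_config(
                seed=21, n_founders=nf, n_generations=0, n_markers=200,
                fixed_effect_spec=(),
            )
            _, geno, _, _ = gp.simulate_dataset(cfg)
            rng = np.random.default_rng(0)
            noise = rng.normal(size=geno.n_individuals)
            s = run_mcmc(geno, noise, McmcConfig(model="BayesA", n_iter=800,
                                                 burn_in=200, seed=6))
            max_eff[nf] = np.max(np.abs(s.effect_mean))
            pred = gebv_from_effects(geno, s)
            fresh = rng.normal(size=geno.n_individuals)
            assert abs(np.corrcoef(pred.gebv, fresh)[0, 1]) < 0.15
        assert max_eff[600] < max_eff[150]

    def test_bayesb_pi_zero_matches_bayesa(self, qtl_data):
        geno, truth, y = qtl_data
        a = run_mcmc(geno, y, McmcConfig(model="BayesA", n_iter=600, burn_in=150, seed=7))
        b = run_mcmc(
            geno, y,
            McmcConfig(model="BayesB", pi_zero=0.0, n_iter=600, burn_in=150, seed=7),
        )
        ga = gebv_from_effects(geno, a).gebv
        gb = gebv_from_effects(geno, b).gebv
        assert np.corrcoef(ga, gb)[0, 1] > 0.98

    def test_bayesc_fixed_pi_zero_reproduces_bayesa_shrinkage(self, qtl_data):
        geno, truth, y = qtl_data
        a = run_mcmc(geno, y, McmcConfig(model="BayesA", n_iter=600, burn_in=150, seed=8))
        c = run_mcmc(
            geno, y,
            McmcConfig(model="BayesC", pi_zero=0.0, fix_pi=True,
                       n_iter=600, burn_in=150, seed=8),
        )
        assert np.corrcoef(
            gebv_from_effects(geno, a).gebv, gebv_from_effects(geno, c).gebv
        )[0, 1] > 0.95

    def test_planted_qtl_top_inclusion(self, qtl_data):
        geno, truth, y = qtl_data
        qtl = truth.qtl_index[0]
        for model in ("BayesB", "BayesC", "BayesR"):
            s = run_mcmc(geno, y, McmcConfig(model=model, n_iter=600, burn_in=150, seed=9))
            assert np.argmax(s.inclusion_prob) == qtl, model

    def test_permuted_y_inclusion_near_prior(self, qtl_data):
        # prior-predictive check: destroying the geno-pheno link leaves
        # inclusion probabilities near the prior 1 - pi
        geno, truth, y = qtl_data
        rng = np.random.default_rng(1)
        yp = rng.permutation(y)
        s = run_mcmc(
            geno, yp,
            McmcConfig(model="BayesB", pi_zero=0.9, n_iter=1000, burn_in=300, seed=10),
        )
        assert abs(np.mean(s.inclusion_prob) - 0.1) < 0.08

    def test_bayesr_occupancy_sums_to_m(self, qtl_data):
        geno, truth, y = qtl_data
        s = run_mcmc(geno, y, McmcConfig(model="BayesR", n_iter=500, burn_in=100, seed=11))
        assert s.component_occupancy.sum() == pytest.approx(geno.n_markers)

    def test_residual_variance_recovery(self):
        # polygenic trait, h2=0.3: posterior sigma_e2 near the true 0.7
        cfg = gp.desk_scale_config(
            seed=31, n_founders=600, n_generations=0, n_markers=200,
            target_h2=0.3, fixed_effect_spec=(),
        )
        _, geno, truth, pheno = gp.simulate_dataset(cfg)
        y = pheno["trait"].to_numpy()
        vals = []
        for seed in range(3):
            s = run_mcmc(
                geno, y, McmcConfig(model="BayesC", n_iter=900, burn_in=300, seed=seed)
            )
            vals.append(s.sigma_e2_mean)
        assert np.mean(vals) == pytest.approx(truth.realized_var_e, rel=0.15)

    def test_zero_variance_y_raises(self, qtl_data):
        geno, _, _ = qtl_data
        with pytest.raises(ValueError, match="zero variance"):
            run_mcmc(geno, np.ones(geno.n_individuals), McmcConfig(n_iter=50, burn_in=10))

    def test_missing_dosage_rejected(self, qtl_data):
        geno, _, y = qtl_data
        miss = gp.inject_missingness(geno, 0.1, seed=1)
        with pytest.raises(ValueError, match="missing"):
            run_mcmc(miss, y, McmcConfig(n_iter=50, burn_in=10))


class TestGebvFromEffects:
    def test_zero_effects_zero_gebv(self, qtl_data):
        geno, truth, y = qtl_data
        s = run_mcmc(geno, y, McmcConfig(model="BayesA", n_iter=200, burn_in=50, seed=1))
        s.effect_mean = np.zeros_like(s.effect_mean)
        assert np.allclose(gebv_from_effects(geno, s).gebv, 0.0)

    def test_single_marker_effect_equals_centred_dosage(self):
        dos = np.array([[0.0], [1.0], [2.0], [1.0]])
        geno = make_geno(dos)
        s = run_mcmc(
            geno, np.array([0.1, 1.0, 2.2, 0.9]),
            McmcConfig(model="BayesA", n_iter=200, burn_in=50, seed=2),
        )
        s.effect_mean = np.array([1.0])
        out = gebv_from_effects(geno, s).gebv
        assert np.allclose(out, dos[:, 0] - s.centering[0])

    def test_matches_brute_force_dot_product(self, qtl_data):
        geno, truth, y = qtl_data
        s = run_mcmc(geno, y, McmcConfig(model="BL", n_iter=300, burn_in=100, seed=3))
        pred = gebv_from_effects(geno, s)
        manual = np.array(
            [
                sum(
                    (geno.dosage[i, j] - s.centering[j]) * s.effect_mean[j]
                    for j in range(geno.n_markers)
                )
                for i in range(5)
            ]
        )
        assert np.allclose(pred.gebv[:5], manual, atol=1e-10)

    def test_marker_mismatch_raises(self, qtl_data):
        geno, truth, y = qtl_data
        s = run_mcmc(geno, y, McmcConfig(model="BayesA", n_iter=200, burn_in=50, seed=4))
        with pytest.raises(ValueError, match="marker count"):
            gebv_from_effects(geno.subset_markers(np.arange(10)), s)


def test_batch_means_mcse_scales_with_noise():
    rng = np.random.default_rng(0)
    small = batch_means_mcse(rng.normal(0, 0.1, 2000))
    large = batch_means_mcse(rng.normal(0, 10.0, 2000))
    assert large > small
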