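"""Generative-model tests: allele-frequency draws, meiosis, mating, phenotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinpgs import simulate
from twinpgs.simulate import (
    SimConfig,
    draw_subpop_frequencies,
    ibd_share,
    mate_assortatively,
    meiosis,
    sample_parent_genotypes,
    simulate_environment_items,
    simulate_phenotype,
    simulate_study,
)


class TestSubpopFrequencies:
    def test_zero_fst_returns_ancestral_exactly(self):
        p = np.array([0.3, 0.3, 0.3])
        out = draw_subpop_frequencies(p, fst=0.0, n_subpops=3, seed=0)
        assert out.shape == (3, 3)
        assert np.array_equal(out, np.tile(p, (3, 1)))

    @pytest.mark.parametrize("fst,expected_var", [(0.1, 0.025), (0.5, 0.125)])
    def test_balding_nichols_moments(self, fst, expected_var):
        # Beta((1-F)/F p, (1-F)/F (1-p)): mean p, variance F p (1-p)
        draws = draw_subpop_frequencies(np.array([0.5]), fst, n_subpops=100_000, seed=3)
        assert draws.mean() == pytest.approx(0.5, abs=0.01)
        assert draws.var() == pytest.approx(expected_var, rel=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="fst"):
            draw_subpop_frequencies(np.array([0.5]), fst=1.0, n_subpops=2)
        with pytest.raises(ValueError, match="empty"):
            draw_subpop_frequencies(np.array([]), fst=0.1, n_subpops=2)


class TestParentGenotypes:
    def test_monomorphic_boundary(self):
        g = sample_parent_genotypes(np.zeros(5), n=100, seed=0)
        assert (g == 0).all()

    def test_binomial_moments(self):
        g = sample_parent_genotypes(np.array([0.5]), n=10_000, seed=1)
        assert g.mean() == pytest.approx(1.0, abs=0.03)
        assert g.var() == pytest.approx(0.5, rel=0.06)

    def test_hardy_weinberg_class_frequencies(self):
        g = sample_parent_genotypes(np.array([0.3]), n=10_000, seed=2).ravel()
        observed = np.bincount(g, minlength=3)
        expected = 10_000 * np.array([0.49, 0.42, 0.09])
        assert stats.chisquare(observed, expected).pvalue > 0.01

    def test_block_ld_induces_adjacent_correlation(self):
        g = sample_parent_genotypes(np.full(20, 0.4), n=8_000, rho_ld=0.6, n_blocks=2, seed=4)
        adj = [np.corrcoef(g[:, j], g[:, j + 1])[0, 1] for j in range(8)]
        assert min(adj) > 0.3
        # marginal distribution still HWE
        counts = np.bincount(g[:, 0], minlength=3)
        expected = 8_000 * np.array([0.36, 0.48, 0.16])
        assert stats.chisquare(counts, expected).pvalue > 0.01

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            sample_parent_genotypes(np.array([0.5]), n=0)


class TestAssortativeMating:
    def test_random_mating_uncorrelated(self, rng):
        ym, yf = rng.standard_normal(5000), rng.standard_normal(5000)
        wife = mate_assortatively(ym, yf, rho_mate=0.0, seed=0)
        assert abs(np.corrcoef(ym, yf[wife])[0, 1]) < 0.05

    def test_perfect_assortment_is_rank_matching(self, rng):
        ym, yf = rng.standard_normal(5000), rng.standard_normal(5000)
        wife = mate_assortatively(ym, yf, rho_mate=1.0, seed=0)
        assert stats.spearmanr(ym, yf[wife]).statistic == pytest.approx(1.0)

    def test_intermediate_assortment_hits_target(self, rng):
        ym, yf = rng.standard_normal(5000), rng.standard_normal(5000)
        wife = mate_assortatively(ym, yf, rho_mate=0.4, seed=0)
        assert 0.35 <= np.corrcoef(ym, yf[wife])[0, 1] <= 0.45

    def test_unequal_pools_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            mate_assortatively(np.zeros(3), np.zeros(4), 0.0)


class TestMeiosis:
    def test_forced_transmission(self):
        t1, t2, _ = meiosis(np.array([2]), np.array([0]), "DZ", seed=0)
        assert t1[0] == 1 and t2[0] == 1

    def test_mendelian_ratios_from_double_heterozygote(self):
        # father=1, mother=1 at every locus: child dosage ~ (1/4, 1/2, 1/4)
        n = 10_000
        t1, _, _ = meiosis(np.ones(n, dtype=int), np.ones(n, dtype=int), "DZ", seed=1)
        observed = np.bincount(t1, minlength=3)
        assert stats.chisquare(observed, n * np.array([0.25, 0.5, 0.25])).pvalue > 0.01

    def test_mz_twins_identical(self, rng):
        f = rng.integers(0, 3, 50)
        m = rng.integers(0, 3, 50)
        t1, t2, rec = meiosis(f, m, "MZ", seed=2)
        assert np.array_equal(t1, t2)
        assert ibd_share(rec) == 1.0

    def test_invalid_dosages_rejected(self):
        with pytest.raises(ValueError, match="dosages"):
            meiosis(np.array([3]), np.array([0]), "DZ")


class TestIbdShare:
    def test_empty_record_rejected(self):
        rec = simulate.TransmissionRecord("DZ", *(np.array([], dtype=np.int8),) * 4)
        with pytest.raises(ValueError, match="empty"):
            ibd_share(rec)

    def test_dz_mean_and_spread(self):
        # mean share 0.5; SD across pairs ~ sqrt(0.125 / L) at L unlinked loci
        L = 200
        st = simulate_study(SimConfig(n_families=600, n_snps=L, prop_mz=0.0, seed=9), items=False)
        shares = st.ibd_shares()
        assert shares.mean() == pytest.approx(0.5, abs=0.01)
        assert shares.std() == pytest.approx(np.sqrt(0.125 / L), rel=0.15)


class TestPhenotypeModel:
    def test_pure_noise_has_unit_variance(self):
        cfg = SimConfig(delta=0, eta=0, sigma_c=0, stratum_effect=0)
        y = simulate_phenotype(np.zeros(20_000), np.zeros(20_000), np.zeros(20_000, int),
                               np.zeros(20_000), cfg, seed=0)
        assert y.var() == pytest.approx(1.0, rel=0.05)

    def test_ols_recovers_direct_effect(self, rng):
        g = rng.standard_normal(20_000)
        cfg = SimConfig(delta=0.7, eta=0.0, sigma_c=0.0)
        y = simulate_phenotype(g, np.zeros_like(g), np.zeros_like(g, dtype=int),
                               np.zeros_like(g), cfg, seed=1)
        slope = np.polyfit(g, y, 1)[0]
        assert slope == pytest.approx(0.7, abs=0.02)

    def test_joint_ols_recovers_direct_and_nurture(self, rng):
        gp = rng.standard_normal(20_000)
        g = 0.5 * gp + np.sqrt(0.75) * rng.standard_normal(20_000)
        cfg = SimConfig(delta=0.5, eta=0.3, sigma_c=0.0)
        y = simulate_phenotype(g, gp, np.zeros_like(g, dtype=int), np.zeros_like(g), cfg, seed=2)
        X = np.column_stack([np.ones_like(g), g, gp])
        coef = np.linalg.lstsq(X, y, rcond=None)[0]
        assert coef[1] == pytest.approx(0.5, abs=0.03)
        assert coef[2] == pytest.approx(0.3, abs=0.03)

    def test_overbudget_variance_rejected(self):
        cfg = SimConfig(delta=0.9, eta=0.9, sigma_c=0.9)
        g = np.random.default_rng(0).standard_normal(100)
        with pytest.raises(ValueError, match="residual variance"):
            simulate_phenotype(g, g, np.zeros(100, int), np.zeros(100), cfg, seed=0)


class TestEnvironmentItems:
    def test_zero_loading_independent_of_parental_pgs(self, rng):
        gp = rng.standard_normal(5000)
        items = simulate_environment_items(gp, enrichment_loading=0.0, seed=0)
        assert abs(np.corrcoef(items["latent_enrichment"], gp)[0, 1]) < 0.03

    def test_half_loading_correlation(self, rng):
        gp = rng.standard_normal(5000)
        items = simulate_environment_items(gp, enrichment_loading=0.5, seed=1)
        assert 0.45 <= np.corrcoef(items["latent_enrichment"], gp)[0, 1] <= 0.55

    def test_item_types(self, rng):
        items = simulate_environment_items(rng.standard_normal(500), 0.3, seed=2)
        assert (items["n_records"] >= 0).all() and (items["n_players"] >= 0).all()
        assert items["concert_freq"].isin(range(5)).all()
        assert items["music_edu_before12"].isin([0, 1]).all()


class TestStudyLevel:
    def test_reproducibility_byte_identical(self):
        cfg = SimConfig(n_families=60, n_snps=40, seed=5)
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_frame_equal(a.env_items, b.env_items)
        pd.testing.assert_series_equal(a.true_pgs, b.true_pgs)

    def test_mz_twins_share_genotypes_and_sex(self, small_study):
        ped = small_study.pedigree
        mz = ped[ped["zygosity"] == "MZ"]
        gm = small_study.genotypes
        pos = {s: i for i, s in enumerate(gm.sample_ids)}
        for _, fam in mz.head(20).iterrows():
            assert np.array_equal(
                gm.dosages[pos[fam["twin1_id"]]], gm.dosages[pos[fam["twin2_id"]]]
            )

    def test_assortative_mating_inflates_dz_correlation(self):
        # single-generation result: sib r = (1 + rho) / (2 + rho) for
        # spousal polygenic-value correlation rho (0.5 at rho = 0)
        cfg = SimConfig(n_families=4000, n_snps=300, prop_mz=0.0, rho_mate=0.9,
                        delta=0.9, sigma_c=0.0, seed=11)
        st = simulate_study(cfg, items=False)
        g = st.true_pgs
        ped = st.pedigree
        rho = np.corrcoef(g[ped["father_id"]], g[ped["mother_id"]])[0, 1]
        r_dz = np.corrcoef(g[ped["twin1_id"]], g[ped["twin2_id"]])[0, 1]
        assert rho > 0.5  # assortment actually produced spousal similarity
        assert r_dz == pytest.approx((1 + rho) / (2 + rho), abs=0.04)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(fst=1.5).validate()
        with pytest.raises(ValueError):
            SimConfig(prop_mz=1.5).validate()
        with pytest.raises(ValueError):
            SimConfig(maf_range=(0.5, 0.1)).validate()
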