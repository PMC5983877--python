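import numpy as np

import pytest
from scipy import stats

from ssimpute.simulate import (
    BlockSpec,
    RegionSpec,
    SimulationConfig,
    assign_missingness,
    draw_sample_sizes,
    latent_rho,
    run_gwas,
    simulate_genotypes,
    simulate_phenotype,
    split_panel,
)


def _block_panel(n, size, r, maf, seed=0):
    regions = [RegionSpec(blocks=[BlockSpec(size, r, maf)])]
    return simulate_genotypes(SimulationConfig(n_individuals=n, regions=regions, seed=seed))


class TestGenotypes:
    def test_block_correlation_hits_target(self):
        panel = _block_panel(5000, 5, 0.9, 0.3, seed=11)
        C = np.corrcoef(panel.dosages, rowvar=False)
        off = C[np.triu_indices(5, 1)]
        assert (off > 0.85).all() and (off < 0.95).all()

    def test_independent_variants_have_null_level_correlation(self):
        regions = [RegionSpec(blocks=[BlockSpec(1, 0.0, 0.3) for _ in range(20)])]
        panel = simulate_genotypes(SimulationConfig(n_individuals=4000, regions=regions, seed=3))
        C = np.corrcoef(panel.dosages, rowvar=False)
        off = np.abs(C[np.triu_indices(20, 1)])
        assert off.mean() < 2 / np.sqrt(4000)

    def test_maf_close_to_target(self):
        panel = _block_panel(8000, 4, 0.5, 0.2, seed=5)
        np.testing.assert_allclose(panel.maf(), 0.2, atol=0.02)

    def test_same_seed_reproduces_matrix(self):
        p1 = _block_panel(500, 3, 0.7, 0.3, seed=9)
        p2 = _block_panel(500, 3, 0.7, 0.3, seed=9)
        np.testing.assert_array_equal(p1.dosages, p2.dosages)

    def test_latent_rho_exceeds_target_and_is_monotone(self):
        lo, hi = latent_rho(0.5, 0.3), latent_rho(0.9, 0.3)
        assert 0.5 < lo < hi
        assert hi > 0.9

    def test_causal_assignment_untyped_with_tagged_block(self):
        config = SimulationConfig(n_individuals=300, n_regions=3, seed=2)
        panel = simulate_genotypes(config)
        v = panel.variants
        for _, grp in v.groupby("chromosome"):
            causal = grp[grp["is_causal"]]
            assert len(causal) == 1
            assert not causal["is_tag"].iloc[0]
            block = grp[grp["block"] == causal["block"].iloc[0]]
            assert block["is_tag"].sum() >= 2


class TestSplitPanel:
    def test_halves_are_disjoint_and_balanced(self):
        panel = _block_panel(1001, 3, 0.5, 0.3)
        rng = np.random.default_rng(1)
        a, b = split_panel(panel, 0.5, rng)
        assert abs(a.n - b.n) <= 1
        assert a.n + b.n == panel.n
        # disjointness: total dosage mass is conserved
        np.testing.assert_allclose(
            a.dosages.sum() + b.dosages.sum(), panel.dosages.sum()
        )


class TestPhenotype:
    def test_null_phenotype_gives_standard_normal_z(self):
        panel = _block_panel(2000, 1, 0.0, 0.3, seed=4)
        rng = np.random.default_rng(104)
        zs = []
        for _ in range(200):
            y = simulate_phenotype(panel, 0, 0.0, rng)
            zs.append(run_gwas(panel, y)["z"].iloc[0])
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.2
        assert zs.std() == pytest.approx(1.0, abs=0.15)

    def test_causal_chi2_matches_noncentrality(self):
        # E[z^2] = 1 + N*h2: at N=12500, h2=0.02 the expectation is 251
        n, h2 = 12_500, 0.02
        assert 1 + n * h2 == 251
        panel = _block_panel(n, 1, 0.0, 0.3, seed=6)
        rng = np.random.default_rng(106)
        chi2 = []
        for _ in range(60):
            y = simulate_phenotype(panel, 0, h2, rng)
            chi2.append(run_gwas(panel, y)["z"].iloc[0] ** 2)
        se = np.std(chi2) / np.sqrt(len(chi2))
        assert np.mean(chi2) == pytest.approx(251, abs=4 * se + 1)

    def test_explained_variance_matches_h2(self):
        panel = _block_panel(20_000, 1, 0.0, 0.3, seed=7)
        y = simulate_phenotype(panel, 0, 0.1, np.random.default_rng(200))
        g = panel.dosages[:, 0]
        r2 = np.corrcoef(g, y)[0, 1] ** 2
        assert r2 == pytest.approx(0.1, abs=0.01)

    def test_total_h2_above_one_rejected(self):
        panel = _block_panel(100, 2, 0.0, 0.3)
        with pytest.raises(ValueError):
            simulate_phenotype(panel, [0, 1], [0.6, 0.6])


class TestSampleSizes:
    @pytest.mark.parametrize("source", ["wide", "narrow"])
    def test_range_and_scaling(self, source):
        rng = np.random.default_rng(0)
        N = draw_sample_sizes(source, 5000, 12_500, rng)
        assert N.min() >= 1 and N.max() <= 12_500
        if source == "narrow":
            # uniform over [50000, 187167] rescaled: minimum around 50000/187167
            assert N.min() > 0.2 * 12_500
        else:
            assert N.min() < 100  # log-uniform reaches tiny sizes

    def test_list_source_resamples_values(self):
        rng = np.random.default_rng(0)
        N = draw_sample_sizes("list", 100, 1000, rng, values=[500, 1000])
        assert set(N.tolist()) <= {500, 1000}

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError):
            draw_sample_sizes("bogus", 10, 100)


class TestMissingness:
    def test_nested_at_theta_one(self):
        rng = np.random.default_rng(0)
        mask = assign_missingness([100, 300], 1000, 1.0, rng)
        assert mask.sum(axis=0).tolist() == [100, 300]
        overlap = (mask[:, 0] & mask[:, 1]).sum()
        assert overlap == 100  # smaller set nested in larger

    def test_identical_masks_at_theta_one_equal_n(self):
        rng = np.random.default_rng(1)
        mask = assign_missingness([200, 200, 200], 500, 1.0, rng)
        assert (mask[:, 0] == mask[:, 1]).all()
        assert (mask[:, 1] == mask[:, 2]).all()

    def test_hypergeometric_overlap_at_theta_zero(self):
        rng = np.random.default_rng(2)
        n = 400
        overlaps = []
        for _ in range(200):
            mask = assign_missingness([n // 2, n // 2], n, 0.0, rng)
            overlaps.append((mask[:, 0] & mask[:, 1]).sum())
        # expected overlap N_k N_l / n = n/4
        assert np.mean(overlaps) == pytest.approx(n / 4, rel=0.05)

    def test_overlap_monotone_in_theta(self):
        rng = np.random.default_rng(3)
        means = []
        for theta in (0.0, 0.5, 1.0):
            ov = []
            for _ in range(50):
                mask = assign_missingness([150, 250], 500, theta, rng)
                ov.append((mask[:, 0] & mask[:, 1]).sum())
            means.append(np.mean(ov))
        assert means[0] < means[1] < means[2]
        assert means[2] == 150

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError):
            assign_missingness([501], 500, 0.5)


class TestRunGwas:
    def test_matches_regression_t_statistic(self):
        panel = _block_panel(2000, 1, 0.0, 0.3, seed=8)
        y = simulate_phenotype(panel, 0, 0.0005, np.random.default_rng(108))
        z = run_gwas(panel, y)["z"].iloc[0]
        g = panel.dosages[:, 0]
        res = stats.linregress(g, y)
        t = res.slope / res.stderr
        # z = r*sqrt(N) approximates the regression t for modest r, large N
        assert z == pytest.approx(t, abs=5e-3)

    def test_constant_genotype_dropped(self):
        panel = _block_panel(100, 2, 0.0, 0.3, seed=9)
        panel.dosages[:, 1] = 1.0
        panel._imputed_cache = None
        out = run_gwas(panel, np.random.default_rng(0).standard_normal(100))
        assert len(out) == 1

    def test_mask_restricts_sample(self):
        panel = _block_panel(500, 1, 0.0, 0.3, seed=10)
        y = np.random.default_rng(1).standard_normal(500)
        mask = np.zeros((500, 1), dtype=bool)
        mask[:200, 0] = True
        out = run_gwas(panel, y, mask=mask)
        assert out["sample_size"].iloc[0] == 200
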