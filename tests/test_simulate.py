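"""Generator fidelity: LD model, phenotype models, regression summaries."""

import json

import numpy as np
import pytest
from scipy import stats

from smrkit.pipeline import AnalysisConfig, run_analysis
from smrkit.simulate import (
    SyntheticScenario, scenario_mafs, simulate_genotypes, simulate_phenotypes,
    simulate_study, summarize_cohort, write_scenario,
)


class TestScenario:
    def test_invalid_architecture(self):
        with pytest.raises(ValueError):
            SyntheticScenario(architecture="epistasis")

    def test_linkage_needs_distinct_causals(self):
        with pytest.raises(ValueError):
            SyntheticScenario(architecture="linkage", causal_index=3,
                              causal_index2=3)

    def test_maf_range_domain(self):
        with pytest.raises(ValueError):
            SyntheticScenario(maf_range=(0.0, 0.6))


class TestSimulateGenotypes:
    def test_fixed_seed_reproducible(self):
        mafs = np.full(5, 0.3)
        g1 = simulate_genotypes(100, 5, mafs, 0.5, np.random.default_rng(9))
        g2 = simulate_genotypes(100, 5, mafs, 0.5, np.random.default_rng(9))
        np.testing.assert_array_equal(g1, g2)

    def test_dosage_domain(self):
        g = simulate_genotypes(200, 4, np.full(4, 0.2), 0.7,
                               np.random.default_rng(1))
        assert set(np.unique(g)) <= {0.0, 1.0, 2.0}

    def test_empirical_maf_within_two_sd(self):
        n = 10_000
        mafs = np.array([0.1, 0.25, 0.4])
        g = simulate_genotypes(n, 3, mafs, 0.5, np.random.default_rng(2))
        emp = g.mean(axis=0) / 2
        sd = np.sqrt(mafs * (1 - mafs) / (2 * n))
        assert np.all(np.abs(emp - mafs) < 2.5 * sd)

    def test_rho_zero_independent(self):
        g = simulate_genotypes(10_000, 6, np.full(6, 0.3), 0.0,
                               np.random.default_rng(3))
        r = np.corrcoef(g, rowvar=False)
        off = r[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_copula_attenuation_of_adjacent_ld(self):
        # at latent rho = 0.9 the thresholded dosage correlation is
        # attenuated: adjacent r^2 lands well below rho^2 but stays strong
        sc = SyntheticScenario()
        g = simulate_genotypes(10_000, sc.n_snps, scenario_mafs(sc),
                               0.9, np.random.default_rng(4))
        r_adj = np.array([np.corrcoef(g[:, i], g[:, i + 1])[0, 1]
                          for i in range(sc.n_snps - 1)])
        assert np.all(r_adj ** 2 > 0.35)
        assert np.all(r_adj ** 2 < 0.81)  # strictly attenuated vs latent

    def test_linkage_causal_pair_ld_near_point_six(self):
        sc = SyntheticScenario(architecture="linkage")
        g = simulate_genotypes(50_000, sc.n_snps, scenario_mafs(sc),
                               sc.ld_rho, np.random.default_rng(5))
        r = np.corrcoef(g[:, sc.causal_index], g[:, sc.causal_index2])[0, 1]
        assert r == pytest.approx(0.6, abs=0.05)


class TestSimulatePhenotypes:
    def test_null_expression_uncorrelated(self):
        sc = SyntheticScenario(architecture="null", b_zx=0.0, b_xy=0.0,
                               n_eqtl_cohort=10_000, n_gwas_cohort=100)
        rng = np.random.default_rng(6)
        mafs = scenario_mafs(sc)
        g_e = simulate_genotypes(sc.n_eqtl_cohort, sc.n_snps, mafs, sc.ld_rho, rng)
        g_g = simulate_genotypes(sc.n_gwas_cohort, sc.n_snps, mafs, sc.ld_rho, rng)
        x, _ = simulate_phenotypes(g_e, g_g, sc, rng)
        r = [abs(np.corrcoef(x, g_e[:, j])[0, 1]) for j in range(sc.n_snps)]
        assert max(r) < 0.05

    def test_pleiotropy_product_rule(self):
        # per-allele trait effect at the causal SNP = b_xy * b_zx
        sc = SyntheticScenario(b_zx=0.5, b_xy=0.3, n_eqtl_cohort=100,
                               n_gwas_cohort=50_000)
        rng = np.random.default_rng(7)
        mafs = scenario_mafs(sc)
        g_e = simulate_genotypes(sc.n_eqtl_cohort, sc.n_snps, mafs, sc.ld_rho, rng)
        g_g = simulate_genotypes(sc.n_gwas_cohort, sc.n_snps, mafs, sc.ld_rho, rng)
        _, y = simulate_phenotypes(g_e, g_g, sc, rng)
        summary = summarize_cohort(g_g, y)
        assert summary.beta[sc.causal_index] == pytest.approx(0.15, abs=0.02)

    def test_linkage_attenuated_association_at_expression_causal(self):
        sc = SyntheticScenario(architecture="linkage", b_zy2=0.3,
                               n_eqtl_cohort=100, n_gwas_cohort=50_000)
        rng = np.random.default_rng(8)
        mafs = scenario_mafs(sc)
        g_e = simulate_genotypes(sc.n_eqtl_cohort, sc.n_snps, mafs, sc.ld_rho, rng)
        g_g = simulate_genotypes(sc.n_gwas_cohort, sc.n_snps, mafs, sc.ld_rho, rng)
        _, y = simulate_phenotypes(g_e, g_g, sc, rng)
        s = summarize_cohort(g_g, y)
        b2 = s.beta[sc.causal_index2]
        b1 = s.beta[sc.causal_index]
        assert b2 == pytest.approx(0.3, abs=0.02)
        # indirect association attenuated roughly by the LD regression slope
        assert 0.0 < b1 < b2

    def test_dimension_mismatch(self):
        sc = SyntheticScenario()
        with pytest.raises(ValueError):
            simulate_phenotypes(np.zeros((10, 5)), np.zeros((10, 4)), sc,
                                np.random.default_rng(0))


class TestSummarizeCohort:
    def test_outcome_equal_to_dosage(self):
        rng = np.random.default_rng(10)
        g = rng.binomial(2, 0.4, size=(500, 3)).astype(float)
        s = summarize_cohort(g, g[:, 1].copy())
        assert s.beta[1] == pytest.approx(1.0)
        assert s.p[1] < 1e-200

    def test_matches_two_pass_covariance_oracle(self):
        rng = np.random.default_rng(11)
        g = rng.binomial(2, 0.3, size=(400, 6)).astype(float)
        y = rng.standard_normal(400)
        s = summarize_cohort(g, y)
        n = len(y)
        for j in range(6):
            x = g[:, j]
            sxx = np.sum((x - x.mean()) ** 2)
            sxy = np.sum((x - x.mean()) * (y - y.mean()))
            beta = sxy / sxx
            resid = (y - y.mean()) - beta * (x - x.mean())
            se = np.sqrt((resid @ resid) / (n - 2) / sxx)
            assert s.beta[j] == pytest.approx(beta, rel=1e-10)
            assert s.se[j] == pytest.approx(se, rel=1e-10)

    def test_permuted_outcome_p_uniform(self):
        rng = np.random.default_rng(12)
        g = rng.binomial(2, 0.3, size=(300, 400)).astype(float)
        y = rng.permutation(g[:, 0])
        s = summarize_cohort(g, y)
        _, ks_p = stats.kstest(s.p[1:], "uniform")  # col 0 is y's ancestor
        assert ks_p > 0.01

    def test_monomorphic_flagged(self):
        g = np.column_stack([np.ones(50), np.arange(50) % 3]).astype(float)
        s = summarize_cohort(g, np.random.default_rng(13).standard_normal(50))
        assert s.monomorphic[0] and not s.monomorphic[1]
        assert np.isnan(s.beta[0]) and np.isnan(s.se[0])


class TestWriteScenario:
    def test_manifest_and_determinism(self, tmp_path):
        sc = SyntheticScenario(n_eqtl_cohort=300, n_gwas_cohort=300,
                               n_ref_panel=100, n_snps=6, seed=21)
        paths1 = write_scenario(sc, tmp_path / "a")
        paths2 = write_scenario(sc, tmp_path / "b")
        for key in ("gwas", "eqtl", "bed", "bim", "fam"):
            b1 = open(paths1[key], "rb").read()
            b2 = open(paths2[key], "rb").read()
            assert b1 == b2, key
        manifest = json.loads(open(paths1["manifest"]).read())
        assert manifest["scenario"]["seed"] == 21

    def test_pipeline_loads_without_harmonization_drops(self, tmp_path):
        sc = SyntheticScenario(n_eqtl_cohort=2000, n_gwas_cohort=2000,
                               n_ref_panel=500, n_snps=8, seed=22)
        paths = write_scenario(sc, tmp_path / "s")
        config = AnalysisConfig(
            gwas_path=paths["gwas"], eqtl_path=paths["eqtl"],
            bfile_prefix=str(tmp_path / "s" / "panel"),
            out_dir=str(tmp_path / "out"),
        )
        results, report = run_analysis(config)
        assert report.n_probes_tested == 1
        assert report.drop_reasons == {}
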