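"""HEIDI: instrument selection, quadratic-form tail, null behaviour."""

import numpy as np
import pytest
from scipy import stats

from smrkit.heidi import (
    HeidiInput, heidi_test, quadform_tail, select_heidi_snps,
)

from conftest import make_panel
from test_harmonize import hsnp


def correlated_panel(r_targets, n_ind=2000, seed=0):
    """Panel whose columns 1.. have prescribed approximate LD with column 0.

    Column i is a copy of the top column with a fraction of entries
    resampled; the realized r is then measured, so tests assert against
    the empirical LD, not the requested one.
    """
    rng = np.random.default_rng(seed)
    top = rng.binomial(2, 0.4, n_ind).astype(float)
    cols = [top]
    for r in r_targets:
        # fraction kept chosen so corr ~ r; then measured exactly in-test
        keep = rng.random(n_ind) < abs(r)
        fresh = rng.binomial(2, 0.4, n_ind).astype(float)
        col = np.where(keep, top, fresh)
        if r < 0:
            col = 2.0 - col
        cols.append(col)
    g = np.column_stack(cols)
    ids = ["top"] + [f"rs{i}" for i in range(len(r_targets))]
    return make_panel(g, snp_ids=ids), ids


class TestSelectHeidiSnps:
    def build(self, r_targets, p_eqtls=None, seed=0):
        panel, ids = correlated_panel(r_targets, seed=seed)
        top = hsnp("top", pos=50)
        p_eqtls = p_eqtls or [1e-6] * len(r_targets)
        others = [hsnp(ids[i + 1], pos=100 + i, p_eqtl=p_eqtls[i])
                  for i in range(len(r_targets))]
        return panel, top, others

    def test_high_ld_with_top_excluded(self):
        panel, top, others = self.build([0.99, 0.5])
        r = np.corrcoef(panel.genotypes, rowvar=False)[0]
        assert r[1] ** 2 > 0.9  # confirm the construction
        sel = select_heidi_snps(others + [top], top, panel)
        assert "rs0" not in {s.snp_id for s in sel.others}

    def test_low_ld_with_top_excluded(self):
        panel, top, others = self.build([0.02, 0.5])
        r = np.corrcoef(panel.genotypes, rowvar=False)[0]
        assert r[1] ** 2 < 0.05
        sel = select_heidi_snps(others + [top], top, panel)
        assert "rs0" not in {s.snp_id for s in sel.others}

    def test_weak_eqtl_instruments_excluded(self):
        panel, top, others = self.build([0.5, 0.5], p_eqtls=[1e-6, 0.01])
        sel = select_heidi_snps(others + [top], top, panel)
        assert {s.snp_id for s in sel.others} == {"rs0"}

    def test_cap_keeps_strongest_eqtls(self):
        m = 30
        rng = np.random.default_rng(3)
        base = rng.standard_normal(5000)
        g = [np.clip(np.round(base * 0.5 + 1), 0, 2)]
        for i in range(m):
            noise = rng.standard_normal(5000)
            g.append(np.clip(np.round(base * 0.4 + noise * 0.35 + 1), 0, 2))
        panel = make_panel(np.column_stack(g),
                           snp_ids=["top"] + [f"rs{i:02d}" for i in range(m)])
        top = hsnp("top", pos=50)
        others = [hsnp(f"rs{i:02d}", pos=100 + i, p_eqtl=10 ** -(4 + i * 0.1))
                  for i in range(m)]
        sel = select_heidi_snps(others + [top], top, panel,
                                r2_min=0.0001, r2_max=0.9999, max_snps=20)
        assert len(sel.others) == 20
        kept_p = sorted(s.p_eqtl for s in sel.others)
        all_p = sorted(s.p_eqtl for s in others)
        assert kept_p == all_p[:20]

    def test_duplicate_instrument_pruned(self):
        # rs0 and rs1 identical (mutual r = 1 > sqrt(0.9)): one survives
        rng = np.random.default_rng(4)
        top = rng.binomial(2, 0.4, 3000).astype(float)
        mid = np.where(rng.random(3000) < 0.55, top,
                       rng.binomial(2, 0.4, 3000).astype(float))
        panel = make_panel(np.column_stack([top, mid, mid.copy()]),
                           snp_ids=["top", "rs0", "rs1"])
        t = hsnp("top", pos=50)
        others = [hsnp("rs0", pos=100, p_eqtl=1e-8),
                  hsnp("rs1", pos=101, p_eqtl=1e-6)]
        sel = select_heidi_snps(others + [t], t, panel)
        assert [s.snp_id for s in sel.others] == ["rs0"]
        off_diag = sel.ld_r_matrix[~np.eye(len(sel.ld_r_matrix), dtype=bool)]
        assert np.all(np.abs(off_diag) < 1.0)


class TestQuadformTail:
    def test_single_weight_is_chisquare(self):
        for x in (0.5, 3.84, 10.0):
            assert quadform_tail(x, [1.0]) == pytest.approx(
                stats.chi2.sf(x, 1), rel=1e-6)

    def test_equal_weights_scaled_chisquare(self):
        # sum of 4 chi2_1 scaled by 0.5 = 0.5 * chi2_4
        assert quadform_tail(3.0, [0.5] * 4) == pytest.approx(
            stats.chi2.sf(6.0, 4), rel=1e-6)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(8)
        for _ in range(3):
            lam = rng.uniform(0.05, 2.0, int(rng.integers(3, 12)))
            draws = (rng.standard_normal((20_000, lam.size)) ** 2) @ lam
            x = float(np.quantile(draws, 0.9))
            mc = float((draws > x).mean())
            se = np.sqrt(mc * (1 - mc) / draws.size)
            assert quadform_tail(x, lam) == pytest.approx(mc, abs=3 * se)

    def test_extreme_x_tends_to_zero(self):
        assert quadform_tail(1e4, [1.0, 0.5, 0.2]) < 1e-10

    def test_nonpositive_x_is_one(self):
        assert quadform_tail(0.0, [1.0, 0.5]) == 1.0


def exact_null_input(m=8, rho=0.5, seed=0):
    """HeidiInput whose d vector follows its modelled null exactly.

    Summary effects are drawn from the multivariate normal the covariance
    model assumes, with a common true ratio b_xy at every SNP and large
    eQTL effects (so the delta-method linearization is accurate).
    """
    rng = np.random.default_rng(seed)
    idx = np.arange(m + 1)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    b_xy = 0.2
    b_e_true = np.full(m + 1, 2.0)
    se_e = np.full(m + 1, 0.02)
    se_g = np.full(m + 1, 0.01)
    chol = np.linalg.cholesky(r)
    b_e = b_e_true + se_e * (chol @ rng.standard_normal(m + 1))
    b_g = b_xy * b_e_true + se_g * (chol @ rng.standard_normal(m + 1))
    snps = [hsnp(f"rs{i}", pos=100 + i, b_gwas=float(b_g[i]),
                 se_gwas=float(se_g[i]), b_eqtl=float(b_e[i]),
                 se_eqtl=float(se_e[i]), p_eqtl=1e-30)
            for i in range(m + 1)]
    return HeidiInput(top=snps[0], others=snps[1:],
                      ld_r_vector=r[0, 1:], ld_r_matrix=r)


class TestHeidiTest:
    def test_below_min_snps_gives_absent_p(self):
        inp = exact_null_input(m=2)
        res = heidi_test(inp, min_snps=3)
        assert res.p_heidi is None and res.n_snps_used == 2

    def test_null_p_uniform(self):
        # under the modelled null, p_HEIDI should be U(0,1)
        pvals = [heidi_test(exact_null_input(seed=s)).p_heidi
                 for s in range(400)]
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_reorder_invariance(self):
        inp = exact_null_input(m=6, seed=3)
        perm = [3, 0, 5, 1, 4, 2]
        shuffled = HeidiInput(
            top=inp.top,
            others=[inp.others[i] for i in perm],
            ld_r_vector=inp.ld_r_vector[[i for i in perm]],
            ld_r_matrix=inp.ld_r_matrix[
                np.ix_([0] + [i + 1 for i in perm], [0] + [i + 1 for i in perm])],
        )
        a, b = heidi_test(inp), heidi_test(shuffled)
        assert a.t_heidi == pytest.approx(b.t_heidi, rel=1e-12)
        assert a.p_heidi == pytest.approx(b.p_heidi, rel=1e-6)

    def test_large_heterogeneity_rejected(self):
        inp = exact_null_input(m=8, seed=5)
        # corrupt one instrument's GWAS effect: ratio departs wildly
        inp.others[3].b_gwas += 1.0
        res = heidi_test(inp)
        assert res.p_heidi < 1e-6

    def test_singular_correlation_ridge_regularized(self, caplog):
        inp = exact_null_input(m=4, rho=0.999999, seed=7)
        with caplog.at_level("WARNING", logger="smrkit.heidi"):
            res = heidi_test(inp)
        assert res.p_heidi is not None and 0.0 < res.p_heidi <= 1.0
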