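"""Backsolved SNP effects, nonlinearA weights, convergence and window variance."""

import numpy as np
import pandas as pd
import pytest

from charrqg import relmat, synthdata
from charrqg.models import ModelSpec
from charrqg.wssgwas import (
    backsolve_snp_effects,
    convergence_stat,
    nonlinearA_weights,
    window_variance,
    wssgblup_iterate,
)


class TestBacksolve:
    def test_zero_gebvs_give_zero_effects(self, rng):
        z = rng.standard_normal((10, 30))
        g = z @ z.T / 30 + np.eye(10) * 0.01
        out = backsolve_snp_effects(np.zeros(10), z, np.ones(30), g,
                                    np.full(30, 0.3))
        np.testing.assert_array_equal(out, 0.0)

    def test_roundtrip_reconstructs_gebvs(self, rng):
        # unblended G: Z a-hat = G G^-1 u = u exactly
        n, m = 50, 200
        p = rng.uniform(0.2, 0.8, m)
        calls = rng.binomial(2, p, (n, m)).astype(float)
        # centring with external (founder) frequencies keeps G full rank;
        # sample-frequency centring would make 1 an exact null vector of G
        z = calls - 2 * p
        denom = relmat.grm_denominator(p)
        g = z @ z.T / denom
        u = z @ rng.standard_normal(m) * 0.05
        ahat = backsolve_snp_effects(u, z, np.ones(m), g, p)
        np.testing.assert_allclose(z @ ahat, u, rtol=1e-8, atol=1e-10)

    def test_linear_in_weights(self, rng):
        n, m = 20, 50
        z = rng.standard_normal((n, m))
        g = z @ z.T / m + np.eye(n)
        u = rng.standard_normal(n)
        p = np.full(m, 0.25)
        d = np.ones(m)
        a1 = backsolve_snp_effects(u, z, d, g, p)
        d2 = d.copy()
        d2[7] = 2.0
        a2 = backsolve_snp_effects(u, z, d2, g, p)
        assert a2[7] == pytest.approx(2 * a1[7])
        np.testing.assert_allclose(np.delete(a2, 7), np.delete(a1, 7))


class TestNonlinearAWeights:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(2.0, 1.0), (0.0, 1.125**-2), (5.0, 1.125**3)],
    )
    def test_closed_forms(self, ratio, expected):
        # construct effects with sd 1 and one entry at the target ratio
        base = np.array([-1.0, 1.0] * 500)
        ahat = np.concatenate([base, [ratio]])
        s = ahat.std()
        w = nonlinearA_weights(ahat)
        # recompute target with the realized sd to keep it exact
        assert w[-1] == pytest.approx(1.125 ** (min(abs(ratio) / s, 5) - 2), abs=1e-12)

    def test_exact_values_with_unit_sd(self):
        # analytic check at sd(a) = 1 exactly
        ahat = np.array([2.0, 0.0, 5.0])
        s = ahat.std()
        w = nonlinearA_weights(ahat / s * np.array([1, 1, 1]))  # rescale -> sd 1 ratios
        ratios = np.abs(ahat / s) / (ahat / s).std()
        np.testing.assert_allclose(w, 1.125 ** (np.minimum(ratios, 5) - 2), atol=1e-12)

    def test_flat_effects_yield_unit_weights(self):
        with pytest.warns(UserWarning, match="sd"):
            w = nonlinearA_weights(np.full(10, 0.3))
        np.testing.assert_array_equal(w, 1.0)

    def test_cap_limits_extreme_effects(self):
        ahat = np.concatenate([np.array([-1.0, 1.0] * 500), [1000.0]])
        w = nonlinearA_weights(ahat, cap_sd=5)
        assert w[-1] == pytest.approx(1.125**3)


class TestConvergenceStat:
    @pytest.mark.parametrize(
        "w,w_prev,expected",
        [
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0),
            ([2.0, 0.0], [0.0, 0.0], 1.0),
            ([1.0, 1.0], [1.0, 0.0], 0.5),
        ],
    )
    def test_direct_arithmetic(self, w, w_prev, expected):
        assert convergence_stat(np.array(w), np.array(w_prev)) == pytest.approx(expected)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            convergence_stat(np.zeros(3), np.ones(3))


class TestWindowVariance:
    def _map(self, chroms, m_per):
        rows = []
        for c in chroms:
            for j in range(m_per):
                rows.append({"snp": f"{c}_{j}", "chrom": c, "pos": (j + 1) * 100})
        return pd.DataFrame(rows)

    def test_zero_effects_zero_windows(self, rng):
        z = rng.standard_normal((15, 40))
        smap = self._map(["chr01", "chr02"], 20)
        w = window_variance(np.zeros(40), z, smap, sigma_g=1.0)
        assert (w["pct_var"] == 0).all()

    def test_single_causal_snp_degenerate_partition(self, rng):
        z = rng.standard_normal((30, 40))
        smap = self._map(["chr01", "chr02"], 20)
        ahat = np.zeros(40)
        ahat[5] = 0.7
        sg = np.var(z[:, 5] * 0.7, ddof=1)
        w = window_variance(ahat, z, smap, sigma_g=sg)
        qwin = w[(w.chrom == "chr01") & (w.window == 0)]
        assert qwin["pct_var"].iloc[0] == pytest.approx(100.0)
        assert (w.drop(qwin.index)["pct_var"] == 0).all()

    def test_windows_never_span_chromosomes(self, rng):
        z = rng.standard_normal((10, 25))
        smap = self._map(["chr01"], 13)
        smap = pd.concat([smap, self._map(["chr02"], 12)], ignore_index=True)
        w = window_variance(rng.standard_normal(25), z, smap, sigma_g=1.0)
        sizes = w.groupby("chrom")["n_snps"].sum()
        assert sizes["chr01"] == 13 and sizes["chr02"] == 12
        assert w[w.chrom == "chr01"]["n_snps"].tolist() == [10, 3]

    def test_chromosome_relabelling_equivariance(self, rng):
        z = rng.standard_normal((20, 30))
        ahat = rng.standard_normal(30)
        m1 = self._map(["chr01", "chr02", "chr03"], 10)
        m2 = m1.copy()
        m2["chrom"] = m2["chrom"].map(
            {"chr01": "w", "chr02": "q", "chr03": "z"}
        )
        w1 = window_variance(ahat, z, m1, 1.0).set_index(["chrom", "window"])
        w2 = window_variance(ahat, z, m2, 1.0).set_index(["chrom", "window"])
        for old, new in [("chr01", "w"), ("chr02", "q"), ("chr03", "z")]:
            np.testing.assert_allclose(
                w1.loc[old]["pct_var"].to_numpy(), w2.loc[new]["pct_var"].to_numpy()
            )

    def test_le_founder_panel_window_sum_near_total(self, rng):
        # independent founders, marker-realised genetic value: window variances
        # should nearly partition the GEBV variance when effects are the truth
        m = 5000
        p = rng.uniform(0.2, 0.8, m)
        calls = rng.binomial(2, p, (1000, m)).astype(float)
        z = calls - 2 * p
        alpha = rng.standard_normal(m) * np.sqrt(1.0 / np.sum(2 * p * (1 - p)))
        sg = np.var(z @ alpha, ddof=1)
        smap = pd.DataFrame(
            {
                "snp": [f"s{j}" for j in range(m)],
                "chrom": np.repeat([f"chr{c:02d}" for c in range(1, 26)], m // 25),
                "pos": np.tile(np.arange(1, m // 25 + 1), 25),
            }
        )
        w = window_variance(alpha, z, smap, sigma_g=sg)
        assert 90.0 <= w["pct_var"].sum() <= 110.0

    def test_nonpositive_sigma_g_rejected(self, rng):
        z = rng.standard_normal((5, 10))
        smap = self._map(["chr01"], 10)
        with pytest.raises(ValueError, match="sigma_g"):
            window_variance(np.zeros(10), z, smap, sigma_g=0.0)


class TestIteration:
    @pytest.fixture(scope="class")
    def gwas_sim(self):
        cfg = synthdata.SimConfig(
            seed=11, n_snps=800, n_families=20, family_size_range=(16, 22),
            n_qtl=1, qtl_variance_fractions=(0.20,), missing_rate=0.0,
            n_intermediate_families=28,
        )
        ped = synthdata.simulate_pedigree(cfg)
        geno = synthdata.gene_drop(ped, cfg)
        pheno, truth, qtl = synthdata.simulate_phenotypes(ped, geno, cfg)
        return ped, geno, pheno, qtl

    def test_weights_sum_preserved_each_iteration(self, gwas_sim):
        ped, geno, pheno, qtl = gwas_sim
        spec = ModelSpec(response="length_t3", fixed_effects=["tank", "sex"], h2=0.30)
        states = wssgblup_iterate(pheno.animals, spec, ped, geno, max_iter=3)
        m = states[0].weights.size
        for s in states:
            assert s.weights.sum() == pytest.approx(m, abs=1e-9)

    def test_qtl_window_sharpens_under_reweighting(self, gwas_sim):
        ped, geno, pheno, qtl = gwas_sim
        spec = ModelSpec(response="length_t3", fixed_effects=["tank", "sex"], h2=0.30)
        states = wssgblup_iterate(pheno.animals, spec, ped, geno, max_iter=2)
        qidx = int(qtl.snp_index.iloc[0])
        pcts = []
        for s in states:
            w = s.windows
            qwin = w[(w.chrom == qtl.chrom.iloc[0])
                     & (w.snp_idx_first <= qidx) & (w.snp_idx_last >= qidx)]
            pcts.append(float(qwin.pct_var.iloc[0]))
        assert pcts[1] > pcts[0]

    def test_null_panel_weights_stay_near_one(self):
        cfg = synthdata.SimConfig(
            seed=5, n_snps=600, n_families=14, family_size_range=(12, 16),
            n_qtl=0, qtl_variance_fractions=(), missing_rate=0.0,
            n_intermediate_families=20,
        )
        ped = synthdata.simulate_pedigree(cfg)
        geno = synthdata.gene_drop(ped, cfg)
        pheno, _, _ = synthdata.simulate_phenotypes(ped, geno, cfg)
        spec = ModelSpec(response="length_t3", fixed_effects=["tank", "sex"], h2=0.30)
        states = wssgblup_iterate(pheno.animals, spec, ped, geno, max_iter=2)
        assert np.abs(states[-1].weights - 1.0).max() < 0.5

    def test_single_iteration_is_unweighted(self, gwas_sim):
        ped, geno, pheno, qtl = gwas_sim
        spec = ModelSpec(response="length_t3", fixed_effects=["tank", "sex"], h2=0.30)
        states = wssgblup_iterate(pheno.animals, spec, ped, geno, max_iter=1)
        assert len(states) == 1
        np.testing.assert_array_equal(states[0].weights, 1.0)
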