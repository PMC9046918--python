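"""Generator properties: pedigree design, gene dropping, phenotype calibration."""

import numpy as np
import pandas as pd
import pytest

from charrqg import synthdata
from charrqg.pedigree import UNKNOWN, inbreeding, sort_pedigree
from charrqg.relmat import GrmSpec, vanraden_grm
from charrqg.synthdata import ConfigError, SimConfig


class TestSimulatePedigree:
    def test_final_generation_size_within_design_bounds(self):
        cfg = SimConfig(seed=1, n_families=44, family_size_range=(27, 63), n_snps=10)
        ped = synthdata.simulate_pedigree(cfg)
        fin = ped.year == ped.year.max()
        assert 44 * 27 <= fin.sum() <= 44 * 63
        fams = synthdata.final_generation_families(ped)
        assert fams.nunique() == 44
        sizes = fams.value_counts()
        assert sizes.min() >= 27 and sizes.max() <= 63

    def test_single_generation_all_founders(self):
        cfg = SimConfig(seed=2, n_generations=1, n_snps=10)
        ped = synthdata.simulate_pedigree(cfg)
        assert np.all(ped.sire == UNKNOWN) and np.all(ped.dam == UNKNOWN)
        assert np.all(inbreeding(ped).f == 0.0)

    def test_fixed_seed_bit_identical(self):
        cfg = SimConfig(seed=33, n_snps=10, n_families=10, family_size_range=(8, 12),
                        n_intermediate_families=20)
        p1 = synthdata.simulate_pedigree(cfg)
        p2 = synthdata.simulate_pedigree(cfg)
        assert list(p1.ids) == list(p2.ids)
        np.testing.assert_array_equal(p1.sire, p2.sire)
        np.testing.assert_array_equal(p1.dam, p2.dam)

    def test_infeasible_family_count_raises(self):
        cfg = SimConfig(seed=3, n_founders=6, n_families=200, n_snps=10,
                        n_intermediate_families=4, intermediate_family_size=2)
        with pytest.raises(ConfigError):
            synthdata.simulate_pedigree(cfg)

    def test_final_generation_f_spans_design_range(self, small_sim):
        ped = sort_pedigree(small_sim.pedigree)
        f = inbreeding(ped).f[ped.year == ped.year.max()]
        assert f.min() <= 0.03
        assert f.max() >= 0.15

    def test_mean_f_matches_design_target(self):
        means = []
        for seed in (10, 11, 12):
            cfg = SimConfig(seed=seed, n_snps=10)
            ped = synthdata.simulate_pedigree(cfg)
            f = inbreeding(ped).f[ped.year == ped.year.max()]
            means.append(f.mean())
        assert abs(np.mean(means) - 0.07) <= 0.02


class TestGeneDrop:
    def test_founder_frequency_conservation(self):
        # founders-only pedigree: sample frequency is unbiased for founder p
        devs = []
        for seed in range(50):
            cfg = SimConfig(seed=seed, n_generations=1, n_founders=40, n_snps=30,
                            missing_rate=0.0, maf_range=(0.3, 0.3001))
            ped = synthdata.simulate_pedigree(cfg)
            g = synthdata.gene_drop(ped, cfg)
            devs.append(g.calls.mean() / 2.0 - 0.3)
        se = np.std(devs) / np.sqrt(len(devs))
        assert abs(np.mean(devs)) < 3 * se + 1e-9

    def test_homozygote_cross_breeds_true(self):
        cfg = SimConfig(seed=4, n_snps=200, n_families=4, family_size_range=(10, 12),
                        missing_rate=0.0, n_intermediate_families=10)
        ped = synthdata.simulate_pedigree(cfg)
        g = synthdata.gene_drop(ped, cfg)
        row = {a: i for i, a in enumerate(g.animal_ids)}
        ped_idx = {a: i for i, a in enumerate(ped.ids)}
        checked = 0
        for a in synthdata.final_generation_families(ped).index:
            i = ped_idx[a]
            s, d = ped.ids[ped.sire[i]], ped.ids[ped.dam[i]]
            both_zero = (g.calls[row[s]] == 0) & (g.calls[row[d]] == 0)
            assert np.all(g.calls[row[a]][both_zero] == 0)
            checked += int(both_zero.sum())
        assert checked > 0

    def test_full_sib_genomic_relationship_near_half(self):
        cfg = SimConfig(seed=5, n_snps=5000, n_families=2, family_size_range=(20, 20),
                        n_generations=2, n_founders=8, missing_rate=0.0,
                        n_intermediate_families=4)
        ped = synthdata.simulate_pedigree(cfg)
        g = synthdata.gene_drop(ped, cfg)
        fams = synthdata.final_generation_families(ped)
        row = {a: i for i, a in enumerate(g.animal_ids)}
        spec = GrmSpec(freqs=g.founder_freqs)
        grm = vanraden_grm(g.calls, spec)
        vals = []
        for fam in fams.unique():
            sibs = [row[a] for a in fams.index[fams == fam]]
            sub = grm[np.ix_(sibs, sibs)]
            vals.append(sub[~np.eye(len(sibs), dtype=bool)].mean())
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_missingness_rate_applied(self, small_sim):
        miss = np.isnan(small_sim.genotypes.calls).mean()
        assert 0.03 < miss < 0.07

    def test_snp_map_covers_chromosomes_and_contigs(self, small_sim):
        chroms = small_sim.genotypes.snp_map["chrom"]
        assert chroms.str.startswith("chr").sum() > 0
        assert chroms.str.startswith("ctg").sum() > 0
        frac_ctg = chroms.str.startswith("ctg").mean()
        assert 0.15 < frac_ctg < 0.27


class TestSimulatePhenotypes:
    def test_maturation_prevalence_hits_target_count(self):
        cfg = SimConfig(seed=6, n_snps=200, maturation_prevalence=0.765)
        ped = synthdata.simulate_pedigree(cfg)
        g = synthdata.gene_drop(ped, cfg)
        ph, _, _ = synthdata.simulate_phenotypes(ped, g, cfg)
        n = len(ph.animals)
        immature = ph.animals["maturation"].sum()
        assert immature == pytest.approx((1 - 0.765) * n, abs=2)

    def test_timepoint_correlations_near_configured(self, small_sim):
        a = small_sim.phenotypes.animals
        r12 = a["length_t1"].corr(a["length_t2"])
        r23 = a["length_t2"].corr(a["length_t3"])
        r13 = a["length_t1"].corr(a["length_t3"])
        assert 0.45 <= r23 <= 0.9
        assert r13 < r23               # far-apart time points correlate less
        assert 0.3 <= r12 <= 0.85

    def test_qtl_variance_matches_plan(self):
        fracs = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_snps=500, n_families=12,
                            family_size_range=(15, 20), n_qtl=1,
                            qtl_variance_fractions=(0.2,), missing_rate=0.0,
                            n_intermediate_families=20)
            ped = synthdata.simulate_pedigree(cfg)
            g = synthdata.gene_drop(ped, cfg)
            ph, truth, qtl = synthdata.simulate_phenotypes(ped, g, cfg)
            q = int(qtl.snp_index.iloc[0])
            dose = g.haplotypes.sum(axis=1).astype(float)
            z = dose[:, q] - 2 * g.founder_freqs[q]
            fracs.append(np.var(z * qtl.effect_length.iloc[0], ddof=1))
        assert np.mean(fracs) == pytest.approx(0.2, rel=0.10)

    def test_realized_h2_calibration(self):
        # variance of planted genetic values over variance net of fixed effects
        ratios = []
        for seed in (20, 21, 22):
            cfg = SimConfig(seed=seed, n_snps=400, missing_rate=0.0)
            ped = synthdata.simulate_pedigree(cfg)
            g = synthdata.gene_drop(ped, cfg)
            ph, truth, _ = synthdata.simulate_phenotypes(ped, g, cfg)
            a = ph.animals
            tb = truth.set_index("animal")["tbv_length"].reindex(a["animal"]).to_numpy()
            genetic = cfg.length_sds[2] * np.sqrt(cfg.h2_length) * tb
            resid = a["length_t3"].to_numpy()
            # adjust for tank and sex by group-demeaning
            df = pd.DataFrame({"y": resid, "tank": a["tank"], "sex": a["sex"]})
            adj = df["y"] - df.groupby(["tank", "sex"])["y"].transform("mean")
            ratios.append(np.var(genetic, ddof=1) / np.var(adj, ddof=1))
        assert abs(np.mean(ratios) - 0.30) <= 0.08

    def test_survival_null_independent_of_f(self):
        rs = []
        for seed in range(30):
            cfg = SimConfig(seed=seed, n_snps=10, survival_association=0.0)
            ped = synthdata.simulate_pedigree(cfg)
            fams = synthdata.final_generation_families(ped)
            fam_f = inbreeding(ped).family_means(fams)
            rng = np.random.default_rng(seed)
            surv = rng.beta(11.25, 3.75, fam_f.size)
            rs.append(np.corrcoef(fam_f.to_numpy(), surv)[0, 1])
        assert np.mean(np.abs(np.array(rs)) < 0.3) >= 0.9

    def test_truth_table_covers_all_animals(self, small_sim):
        assert set(small_sim.true_values["animal"]) == set(small_sim.pedigree.ids)
        assert set(small_sim.phenotypes.animals["animal"]) <= set(small_sim.pedigree.ids)
        assert set(small_sim.genotypes.animal_ids) <= set(small_sim.pedigree.ids)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            SimConfig(qtl_variance_fractions=(0.6, 0.5), n_qtl=2)
        with pytest.raises(ConfigError):
            SimConfig(h2_length=1.2)
        with pytest.raises(ConfigError):
            SimConfig(maf_range=(0.0, 0.5))

    def test_simulate_deterministic_end_to_end(self):
        cfg = SimConfig(seed=77, n_snps=60, n_families=6, family_size_range=(8, 10),
                        n_intermediate_families=12)
        s1 = synthdata.simulate(cfg)
        s2 = synthdata.simulate(cfg)
        np.testing.assert_array_equal(
            np.nan_to_num(s1.genotypes.calls, nan=-1),
            np.nan_to_num(s2.genotypes.calls, nan=-1),
        )
        pd.testing.assert_frame_equal(s1.phenotypes.animals, s2.phenotypes.animals)
        pd.testing.assert_frame_equal(s1.true_values, s2.true_values)
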