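"""Heterozygosity, Weir-Cockerham Fst, genotype PCA and family correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from charrqg.diversity import (
    family_correlations,
    fst_components,
    genotype_pca,
    group_heterozygosity,
    pairwise_fst,
)


def brute_force_theta(calls_a, calls_b):
    """Independent transcription of the Weir & Cockerham (1984) estimator.

    Loops locus by locus with the r=2 component formulas written out
    directly from the variance-component definitions; aggregation is the
    ratio of summed components.
    """
    suma = sumall = 0.0
    m = calls_a.shape[1]
    for j in range(m):
        xa = calls_a[:, j]
        xb = calls_b[:, j]
        xa = xa[~np.isnan(xa)]
        xb = xb[~np.isnan(xb)]
        if xa.size == 0 or xb.size == 0:
            continue
        r = 2
        n1, n2 = len(xa), len(xb)
        p1 = xa.sum() / (2 * n1)
        p2 = xb.sum() / (2 * n2)
        h1 = np.mean(xa == 1)
        h2 = np.mean(xb == 1)
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        if nbar <= 1:
            continue
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        if a + b + c == 0:
            continue
        suma += a
        sumall += a + b + c
    return suma / sumall


class TestHeterozygosity:
    def test_all_heterozygous_group(self, geno_factory):
        g = geno_factory(np.ones((4, 10)), populations=["x"] * 4)
        t = group_heterozygosity(g)
        assert t.loc[0, "ho"] == 1.0
        assert t.loc[0, "he"] == pytest.approx(0.5)

    def test_clonal_homozygous_group(self, geno_factory):
        g = geno_factory(np.full((3, 5), 2.0))
        t = group_heterozygosity(g)
        assert t.loc[0, "ho"] == 0.0
        assert t.loc[0, "he"] == 0.0

    def test_family_ho_spreads_with_inbreeding(self, small_sim):
        from charrqg.pedigree import inbreeding, sort_pedigree

        g = small_sim.genotypes
        mask = np.array([f == f and f is not None for f in g.families])
        fam_div = group_heterozygosity(g.take_animals(mask), "family")
        spread = fam_div["ho"].max() - fam_div["ho"].min()
        assert spread >= 0.02           # families differ in diversity
        # and Ho declines with family inbreeding
        ped = sort_pedigree(small_sim.pedigree)
        fam_f = inbreeding(ped).family_means(small_sim.families)
        merged = fam_div.set_index("group").join(fam_f)
        r = np.corrcoef(merged["ho"], merged["mean_F"])[0, 1]
        assert r < 0.0

    def test_he_never_above_half(self, geno_factory, rng):
        g = geno_factory(rng.integers(0, 3, (20, 50)).astype(float))
        t = group_heterozygosity(g)
        assert (t["he"] <= 0.5 + 1e-12).all()


class TestFst:
    def test_fixed_alternate_alleles_give_theta_one(self, geno_factory):
        calls = np.vstack([np.zeros((30, 40)), np.full((30, 40), 2.0)])
        g = geno_factory(calls, populations=["A"] * 30 + ["B"] * 30)
        fst = pairwise_fst(g)
        assert fst.loc["A", "B"] == pytest.approx(1.0, abs=0.02)

    def test_duplicated_group_near_zero(self, geno_factory, rng):
        base = rng.binomial(2, rng.uniform(0.1, 0.9, 500), (100, 500)).astype(float)
        pops = ["A"] * 50 + ["B"] * 50
        g = geno_factory(base, populations=pops)
        fst = pairwise_fst(g)
        assert abs(fst.loc["A", "B"]) < 0.01

    def test_matches_brute_force_oracle(self, geno_factory, rng):
        p1 = rng.uniform(0.1, 0.9, 50)
        p2 = np.clip(p1 + rng.normal(0, 0.15, 50), 0.02, 0.98)
        ca = rng.binomial(2, p1, (20, 50)).astype(float)
        cb = rng.binomial(2, p2, (20, 50)).astype(float)
        g = geno_factory(np.vstack([ca, cb]), populations=["A"] * 20 + ["B"] * 20)
        theta = pairwise_fst(g).loc["A", "B"]
        assert theta == pytest.approx(brute_force_theta(ca, cb), abs=1e-12)

    def test_relabelling_equivariance(self, geno_factory, rng):
        calls = rng.binomial(2, 0.4, (60, 80)).astype(float)
        pops = np.array(["A"] * 20 + ["B"] * 20 + ["C"] * 20, dtype=object)
        g1 = geno_factory(calls, populations=pops)
        ren = {"A": "Z", "B": "Y", "C": "X"}
        g2 = geno_factory(calls, populations=[ren[p] for p in pops])
        f1 = pairwise_fst(g1)
        f2 = pairwise_fst(g2)
        for pa, pb in itertools.combinations("ABC", 2):
            assert f1.loc[pa, pb] == pytest.approx(f2.loc[ren[pa], ren[pb]], abs=1e-15)

    def test_exclude_group(self, geno_factory, rng):
        calls = rng.binomial(2, 0.4, (30, 40)).astype(float)
        g = geno_factory(calls, populations=["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        fst = pairwise_fst(g, exclude=("C",))
        assert list(fst.index) == ["A", "B"]


class TestPca:
    def test_planted_clusters_separate_on_pc1(self, geno_factory, rng):
        p1 = rng.uniform(0.05, 0.95, 300)
        p2 = np.clip(p1 + rng.choice([-0.4, 0.4], 300), 0.02, 0.98)
        calls = np.vstack(
            [rng.binomial(2, p1, (25, 300)), rng.binomial(2, p2, (25, 300))]
        ).astype(float)
        g = geno_factory(calls)
        res = genotype_pca(g, k=2)
        pc1 = res.scores[:, 0]
        side = pc1 > np.median(pc1)
        assert side[:25].all() != side[25:].all()
        assert side[:25].sum() in (0, 25)

    def test_identical_animals_flagged_degenerate(self, geno_factory):
        g = geno_factory(np.ones((6, 20)))
        res = genotype_pca(g, k=2)
        assert res.degenerate
        assert np.all(res.var_frac == 0)

    def test_duplicate_rows_get_duplicate_scores(self, geno_factory, rng):
        calls = rng.integers(0, 3, (10, 60)).astype(float)
        calls[9] = calls[0]
        res = genotype_pca(geno_factory(calls), k=3)
        np.testing.assert_allclose(res.scores[0], res.scores[9], atol=1e-10)

    def test_variance_fractions_sorted_and_sum_to_one_at_full_rank(
        self, geno_factory, rng
    ):
        calls = rng.integers(0, 3, (8, 100)).astype(float)
        res = genotype_pca(geno_factory(calls), k=8)
        assert np.all(np.diff(res.var_frac) <= 1e-12)
        assert res.var_frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_k_beyond_rank_raises(self, geno_factory, rng):
        g = geno_factory(rng.integers(0, 3, (5, 30)).astype(float))
        with pytest.raises(ValueError, match="rank"):
            genotype_pca(g, k=6)


class TestFamilyCorrelations:
    def _table(self, ho, fam=None):
        fam = fam or [f"f{i}" for i in range(len(ho))]
        return pd.DataFrame({"group": fam, "n": 10, "ho": ho, "he": ho})

    def test_exact_linear_relation_gives_minus_one(self):
        f = pd.Series([0.02, 0.05, 0.10, 0.15], index=[f"f{i}" for i in range(4)])
        div = self._table(list(0.4 - f.to_numpy()))
        surv = pd.Series(0.8, index=f.index)
        out = family_correlations(div, f, surv)
        r_ho_f = out.set_index("pair").loc["ho~f", "r"]
        assert r_ho_f == pytest.approx(-1.0)

    def test_zero_variance_reported_as_nan(self):
        f = pd.Series([0.05] * 4, index=[f"f{i}" for i in range(4)])
        div = self._table([0.3, 0.32, 0.35, 0.31])
        surv = pd.Series([0.7, 0.8, 0.75, 0.72], index=f.index)
        out = family_correlations(div, f, surv).set_index("pair")
        assert np.isnan(out.loc["f~survival", "r"])

    def test_null_survival_correlation_is_small_in_most_replicates(self, rng):
        hits = 0
        reps = 60
        for _ in range(reps):
            f = pd.Series(rng.uniform(0.02, 0.18, 44),
                          index=[f"f{i}" for i in range(44)])
            surv = pd.Series(rng.beta(11.25, 3.75, 44), index=f.index)
            div = self._table(list(rng.uniform(0.3, 0.42, 44)))
            out = family_correlations(div, f, surv).set_index("pair")
            if abs(out.loc["f~survival", "r"]) < 0.3:
                hits += 1
        assert hits >= 0.9 * reps
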