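"""Synthetic breeding-programme generator.

Emulates the statistical structure of a small salmonid breeding nucleus so
the whole analysis chain is testable without any data download:

* a multi-generation pedigree whose final year class consists of a fixed
  number of full-sib families (default 44, sizes uniform on 27-63), with
  matings chosen so final-generation pedigree inbreeding spans roughly
  0.03-0.25 with a design mean near 0.07;
* gene dropping of a few thousand biallelic SNPs over 39 chromosomes plus
  unplaced contigs, founder haplotypes at linkage equilibrium, Haldane
  recombination (1 Morgan per chromosome), uniform missingness;
* length at three correlated time points (narrow-sense h2 configurable,
  default 0.30) with tank and sex effects and a handful of QTL shared with
  a binary maturation trait simulated on the liability scale (liability h2
  default 0.28, residual variance 1);
* family-level eyed-stage embryo survival, beta-distributed, optionally
  correlated with family mean inbreeding (a zero association is the null
  scenario).

All randomness derives from ``SimConfig.seed``; a fixed seed gives a
bit-identical :class:`SimOutput`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .genoqc import GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree, inbreeding, sort_pedigree, a_matrix

__all__ = ["SimConfig", "SimOutput", "PhenotypeTable", "simulate",
           "simulate_pedigree", "gene_drop", "simulate_phenotypes"]


class ConfigError(ValueError):
    """Raised for infeasible or inconsistent simulation settings."""


@dataclass
class SimConfig:
    """Study-condition parameters of the simulated breeding programme."""

    n_founders: int = 60
    n_generations: int = 4
    n_families: int = 44
    family_size_range: tuple = (27, 63)
    n_snps: int = 5000
    n_chromosomes: int = 39
    maf_range: tuple = (0.05, 0.5)
    n_qtl: int = 5
    qtl_variance_fractions: tuple = (0.20, 0.05, 0.04, 0.03, 0.02)
    h2_length: float = 0.30
    h2_maturation_liability: float = 0.28
    timepoint_correlations: tuple = (
        (1.00, 0.60, 0.45),
        (0.60, 1.00, 0.74),
        (0.45, 0.74, 1.00),
    )
    maturation_prevalence: float = 0.765    # fraction reaching maturity at 2+ years
    survival_association: float = 0.0       # corr(latent survival, family mean F); 0 = null
    seed: int = 0
    # ancillary structure
    unplaced_fraction: float = 0.21
    n_unplaced_contigs: int = 25
    map_length_morgans: float = 1.0
    contig_map_length: float = 0.05
    missing_rate: float = 0.05
    n_intermediate_families: int = 40
    intermediate_family_size: int = 5
    target_mean_f: float = 0.07
    survival_mean: float = 0.75
    survival_concentration: float = 15.0
    length_means: tuple = (190.0, 300.0, 430.0)
    length_sds: tuple = (23.0, 30.0, 42.0)
    n_tanks: int = 8
    tank_sd_frac: float = 0.15              # tank effect sd as fraction of trait sd
    sex_dimorphism: float = 0.05            # male length advantage as fraction of mean

    def __post_init__(self):
        for frac in (
            self.h2_length,
            self.h2_maturation_liability,
            self.maturation_prevalence,
            self.missing_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must lie in [0, 1]")
        lo, hi = self.family_size_range
        if lo < 1 or hi < lo:
            raise ConfigError("family_size_range must be positive and ordered")
        if len(self.qtl_variance_fractions) != self.n_qtl:
            raise ConfigError("need one variance fraction per QTL")
        if sum(self.qtl_variance_fractions) >= 1.0:
            raise ConfigError("QTL variance fractions must sum to < 1")
        if not (0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")


@dataclass
class PhenotypeTable:
    """Animal-level records plus family-level eyed-stage survival."""

    animals: pd.DataFrame          # animal, family, tank, sex, length_t1..t3, maturation
    family_survival: pd.DataFrame  # family, survival


@dataclass
class SimOutput:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    true_values: pd.DataFrame
    qtl: pd.DataFrame
    families: pd.Series            # final-generation animal -> family label
    config: SimConfig = field(repr=False, default=None)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Build the breeding-programme pedigree.

    Founders (generation 0) are unrelated; intermediate generations mate
    with deliberate sire reuse so the last parental generation contains
    full-sib, half-sib and cousin pairs.  The final generation's parent
    pairs are then chosen by matching each family's target inbreeding
    (drawn from a beta law with the design mean) to the closest available
    parental kinship, which yields the intended spread of F.
    """
    if config.n_founders < 2:
        raise ConfigError("need at least two founders")
    if config.n_generations < 1:
        raise ConfigError("need at least one generation")
    rng = _rng(config, 0)
    ids: list[str] = [f"F{i:04d}" for i in range(config.n_founders)]
    sire = [UNKNOWN] * config.n_founders
    dam = [UNKNOWN] * config.n_founders
    year = [0] * config.n_founders
    sex = list(rng.integers(0, 2, config.n_founders))  # 0 female, 1 male
    prev_gen = list(range(config.n_founders))
    if config.n_generations == 1:
        return Pedigree(
            np.array(ids, object),
            np.array(sire, np.int64),
            np.array(dam, np.int64),
            np.array(year, np.int64),
        )

    def add_animal(s, d, y, sx):
        idx = len(ids)
        ids.append(f"G{y}_{idx:05d}")
        sire.append(s)
        dam.append(d)
        year.append(y)
        sex.append(sx)
        return idx

    # intermediate generations: limited sire pool creates half-sib structure
    for gen in range(1, config.n_generations - 1):
        males = [i for i in prev_gen if sex[i] == 1]
        females = [i for i in prev_gen if sex[i] == 0]
        if not males or not females:
            raise ConfigError("a generation lacks one sex entirely")
        n_fam = config.n_intermediate_families
        sire_pool = rng.choice(males, size=max(len(males) // 2, 1), replace=False)
        fam_sires = rng.choice(sire_pool, size=n_fam, replace=True)
        fam_dams = rng.choice(females, size=n_fam, replace=len(females) < n_fam)
        new_gen = []
        for s, d in zip(fam_sires, fam_dams):
            for k in range(config.intermediate_family_size):
                new_gen.append(add_animal(int(s), int(d), gen, k % 2))
        prev_gen = new_gen

    # final generation: kinship-matched parent pairs
    ped_now = Pedigree(
        np.array(ids, object),
        np.array(sire, np.int64),
        np.array(dam, np.int64),
        np.array(year, np.int64),
    )
    A = a_matrix(ped_now)
    males = [i for i in prev_gen if sex[i] == 1]
    females = [i for i in prev_gen if sex[i] == 0]
    pairs = [(m, f) for m in males for f in females]
    if len(pairs) < config.n_families:
        raise ConfigError("more families requested than available parent pairs")
    kin = np.array([0.5 * A[m, f] for m, f in pairs])
    # target F per family: beta law scaled to [0, 0.25] with the design mean
    mean_t = config.target_mean_f / 0.25
    a_par = 1.2
    b_par = a_par * (1.0 - mean_t) / mean_t
    targets = np.sort(rng.beta(a_par, b_par, config.n_families) * 0.25)[::-1]
    usage: dict[int, int] = {}
    taken = np.zeros(len(pairs), bool)
    chosen = []
    order = rng.permutation(len(pairs))
    for tgt in targets:
        best, best_diff = -1, np.inf
        for j in order:
            if taken[j]:
                continue
            m, f = pairs[j]
            if usage.get(m, 0) >= 3 or usage.get(f, 0) >= 3:
                continue
            diff = abs(kin[j] - tgt)
            if diff < best_diff:
                best, best_diff = j, diff
                if diff == 0.0:
                    break
        if best < 0:
            raise ConfigError("ran out of eligible parent pairs")
        taken[best] = True
        m, f = pairs[best]
        usage[m] = usage.get(m, 0) + 1
        usage[f] = usage.get(f, 0) + 1
        chosen.append((m, f))
    lo, hi = config.family_size_range
    final_year = config.n_generations - 1
    for m, f in chosen:
        size = int(rng.integers(lo, hi + 1))
        for k in range(size):
            add_animal(m, f, final_year, k % 2)
    ped = Pedigree(
        np.array(ids, object),
        np.array(sire, np.int64),
        np.array(dam, np.int64),
        np.array(year, np.int64),
    )
    return sort_pedigree(ped)


def final_generation_families(ped: Pedigree) -> pd.Series:
    """Family label (sire, dam pair) for animals of the last year class."""
    last = ped.year.max()
    sel = np.flatnonzero(ped.year == last)
    pair_ids: dict[tuple, str] = {}
    fams = []
    for i in sel:
        key = (ped.sire[i], ped.dam[i])
        if key not in pair_ids:
            pair_ids[key] = f"fam{len(pair_ids) + 1:03d}"
        fams.append(pair_ids[key])
    return pd.Series(fams, index=ped.ids[sel], name="family")


def _snp_map(config: SimConfig, rng) -> pd.DataFrame:
    n_unplaced = int(round(config.n_snps * config.unplaced_fraction))
    n_placed = config.n_snps - n_unplaced
    chrom_of = np.sort(rng.integers(0, config.n_chromosomes, n_placed))
    rows = []
    for c in range(config.n_chromosomes):
        pos = np.sort(rng.integers(1, 25_000_000, int((chrom_of == c).sum())))
        for pp in pos:
            rows.append((f"chr{c + 1:02d}", int(pp), config.map_length_morgans))
    if n_unplaced:
        ctg_of = np.sort(rng.integers(0, config.n_unplaced_contigs, n_unplaced))
        for c in range(config.n_unplaced_contigs):
            pos = np.sort(rng.integers(1, 100_000, int((ctg_of == c).sum())))
            for pp in pos:
                rows.append((f"ctg{c + 1:03d}", int(pp), config.contig_map_length))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "map_len"])
    df.insert(0, "snp", [f"snp{i + 1:05d}" for i in range(len(df))])
    return df


def gene_drop(ped: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Drop founder haplotypes through the pedigree with Haldane recombination.

    Founder allele frequencies are uniform on ``maf_range``; haplotypes are
    at linkage equilibrium, so LD arises purely from co-segregation within
    the pedigree.  Missing calls are masked uniformly at random.  The
    founder frequencies and founder haplotypes are attached as attributes
    for calibration checks.
    """
    ped = sort_pedigree(ped)
    rng = _rng(config, 1)
    smap = _snp_map(config, rng)
    m = len(smap)
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], m)
    # genetic position of each SNP within its chromosome block
    blocks = []
    start = 0
    for chrom, grp in smap.groupby("chrom", sort=False):
        length = float(grp["map_len"].iloc[0])
        span = max(int(grp["pos"].max()), 1)
        gpos = grp["pos"].to_numpy() / span * length
        blocks.append((start, start + len(grp), length, gpos))
        start += len(grp)
    n = ped.n
    hap = np.zeros((n, 2, m), dtype=np.int8)

    def gamete(parent: int) -> np.ndarray:
        out = np.empty(m, dtype=np.int8)
        for lo, hi, length, gpos in blocks:
            phase = rng.integers(0, 2)
            n_xo = rng.poisson(length)
            if n_xo == 0:
                out[lo:hi] = hap[parent, phase, lo:hi]
                continue
            xo = np.sort(rng.uniform(0.0, length, n_xo))
            which = (phase + np.searchsorted(xo, gpos)) % 2
            seg = hap[parent, :, lo:hi]
            out[lo:hi] = seg[which, np.arange(hi - lo)]
        return out

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        for h, parent in enumerate((s, d)):
            if parent == UNKNOWN:
                hap[i, h] = (rng.random(m) < freqs).astype(np.int8)
            else:
                hap[i, h] = gamete(parent)
    calls = hap.sum(axis=1).astype(float)
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = np.nan
    fams = final_generation_families(ped)
    fam_arr = pd.Series(ped.ids).map(fams).to_numpy(object)
    g = GenotypeMatrix(
        ped.ids.copy(),
        smap[["snp", "chrom", "pos"]].copy(),
        calls,
        populations=np.array([f"YC{y}" for y in ped.year], object),
        families=fam_arr,
    )
    g.founder_freqs = freqs
    g.haplotypes = hap
    return g


def simulate_phenotypes(
    ped: Pedigree, genotypes: GenotypeMatrix, config: SimConfig
) -> tuple[PhenotypeTable, pd.DataFrame, pd.DataFrame]:
    """Phenotypes for the final generation; returns (table, truth, qtl).

    The additive-genetic scale is standardised (total genetic variance 1 in
    expectation): QTL effects are sized from founder frequencies to their
    planned variance fractions and a pedigree polygenic term supplies the
    remainder.  Lengths add tank, sex and scaled residuals so narrow-sense
    h2 (net of fixed effects) matches ``h2_length``; maturation liability
    adds a standard-normal residual and is thresholded at the sample
    quantile giving the configured prevalence.
    """
    rng = _rng(config, 2)
    ped = sort_pedigree(ped)
    fams = final_generation_families(ped)
    fin = ped.index_of(fams.index)
    n_all = ped.n

    freqs = getattr(genotypes, "founder_freqs", None)
    if freqs is None:
        from .relmat import allele_frequencies

        freqs = allele_frequencies(genotypes.calls)
    dose = getattr(genotypes, "haplotypes", None)
    if dose is not None:
        dose = dose.sum(axis=1).astype(float)   # complete genotypes, pre-missingness
    else:
        dose = np.nan_to_num(genotypes.calls, nan=0.0)
    # order genotype rows by pedigree
    row_of = {a: i for i, a in enumerate(genotypes.animal_ids)}
    geno_rows = np.array([row_of[a] for a in ped.ids])
    dose = dose[geno_rows]

    fracs = np.asarray(config.qtl_variance_fractions, float)
    # QTL are drawn among common placed variants (founder frequency 0.15-0.5):
    # a near-rare causal allele can lose half its variance to drift through
    # the parental bottleneck and is not a usable mapping target
    common = (freqs >= 0.15) & (freqs <= 0.85)
    placed = np.flatnonzero(
        genotypes.snp_map["chrom"].str.startswith("chr").to_numpy() & common
    )
    if placed.size < config.n_qtl:
        placed = np.arange(genotypes.n_snps)
    # spread QTL across distinct chromosomes where possible
    chroms = genotypes.snp_map["chrom"].to_numpy()
    qtl_idx = []
    for c in pd.unique(chroms[placed]):
        cand = placed[chroms[placed] == c]
        qtl_idx.append(int(rng.choice(cand)))
        if len(qtl_idx) == config.n_qtl:
            break
    qtl_idx = np.array(qtl_idx[: config.n_qtl], dtype=np.int64)
    p_q = freqs[qtl_idx]
    two_pq = 2.0 * p_q * (1.0 - p_q)

    def qtl_effects():
        mag = np.sqrt(fracs / two_pq)
        return mag * rng.choice([-1.0, 1.0], size=len(fracs))

    alpha_len = qtl_effects()
    alpha_mat = qtl_effects()
    zq = dose[:, qtl_idx] - 2.0 * p_q[None, :]
    # calibrate each QTL's realised variance share over the phenotyped cohort
    fin_cal = ped.index_of(fams.index)
    for k in range(len(fracs)):
        sd_k = np.std(zq[fin_cal, k] * alpha_len[k])
        if sd_k > 1e-12:
            alpha_len[k] *= np.sqrt(fracs[k]) / sd_k
        sd_k = np.std(zq[fin_cal, k] * alpha_mat[k])
        if sd_k > 1e-12:
            alpha_mat[k] *= np.sqrt(fracs[k]) / sd_k

    # polygenic background realised through the markers themselves: small
    # effects on every non-QTL SNP, scaled so the background variance under
    # founder linkage equilibrium equals the remainder of sigma_g^2 = 1.
    bg_idx = np.setdiff1d(np.arange(genotypes.n_snps), qtl_idx)
    p_bg = freqs[bg_idx]
    z_bg = dose[:, bg_idx] - 2.0 * p_bg[None, :]
    bg_scale = np.sum(2.0 * p_bg * (1.0 - p_bg))

    def polygenic(var_poly: float) -> np.ndarray:
        beta = rng.normal(0.0, np.sqrt(var_poly / bg_scale), bg_idx.size)
        g_bg = z_bg @ beta
        sd = np.std(g_bg[fin_cal])
        if sd > 1e-12:                  # realised background variance on plan
            g_bg *= np.sqrt(var_poly) / sd
        return g_bg

    var_poly = 1.0 - fracs.sum()
    g_len = zq @ alpha_len + polygenic(var_poly)
    sg_mat = config.h2_maturation_liability / (1.0 - config.h2_maturation_liability)
    g_mat = zq @ alpha_mat + polygenic(var_poly)
    # calibrate: realized genetic variance over the phenotyped cohort equals
    # the plan exactly, so realized h2 matches the configured value instead of
    # drifting with the random draw of marker effects and QTL frequencies
    fin_pre = ped.index_of(fams.index)
    scale_len = 1.0 / max(np.std(g_len[fin_pre]), 1e-12)
    scale_mat = np.sqrt(sg_mat) / max(np.std(g_mat[fin_pre]), 1e-12)
    g_len = g_len * scale_len
    g_mat = g_mat * scale_mat
    alpha_len = alpha_len * scale_len
    alpha_mat_out = alpha_mat * scale_mat

    n_fin = fin.size
    tank = rng.integers(0, config.n_tanks, n_fin)
    sexes = np.where(rng.random(n_fin) < 0.5, "M", "F")
    h2 = config.h2_length
    rho = np.asarray(config.timepoint_correlations, float)
    r_e = np.clip((rho - h2) / (1.0 - h2), 0.0, 0.999)
    np.fill_diagonal(r_e, 1.0)
    chol = np.linalg.cholesky(r_e)
    eps = rng.standard_normal((n_fin, 3)) @ chol.T
    lengths = {}
    for t in range(3):
        mu, sd = config.length_means[t], config.length_sds[t]
        tank_eff = rng.normal(0.0, config.tank_sd_frac * sd, config.n_tanks)
        sex_eff = np.where(sexes == "M", config.sex_dimorphism * mu, 0.0)
        lengths[f"length_t{t + 1}"] = (
            mu
            + tank_eff[tank]
            + sex_eff
            + sd * np.sqrt(h2) * g_len[fin]
            + sd * np.sqrt(1.0 - h2) * eps[:, t]
        )
    liab = g_mat[fin] + rng.standard_normal(n_fin)
    thresh = np.quantile(liab, config.maturation_prevalence)
    maturation = (liab > thresh).astype(int)   # 0 = mature, 1 = non-mature
    animals = pd.DataFrame(
        {
            "animal": fams.index,
            "family": fams.to_numpy(),
            "tank": pd.Series(tank).map(lambda t: f"tank{t + 1}").to_numpy(),
            "sex": sexes,
            **lengths,
            "maturation": maturation,
        }
    )

    fres = inbreeding(ped)
    fam_f = fres.family_means(fams)
    fam_names = fam_f.index.to_numpy()
    mean_s = config.survival_mean
    conc = config.survival_concentration
    a_b = (mean_s * conc, (1.0 - mean_s) * conc)
    if config.survival_association == 0.0:
        surv = rng.beta(*a_b, size=len(fam_names))
    else:
        zf = (fam_f - fam_f.mean()) / max(fam_f.std(), 1e-12)
        rho_s = np.clip(config.survival_association, -0.999, 0.999)
        latent = rho_s * zf.to_numpy() + np.sqrt(1 - rho_s**2) * rng.standard_normal(
            len(fam_names)
        )
        surv = sstats.beta.ppf(sstats.norm.cdf(latent), *a_b)
    family_survival = pd.DataFrame({"family": fam_names, "survival": surv})

    truth = pd.DataFrame(
        {
            "animal": ped.ids,
            "tbv_length": g_len,
            "tbv_maturation": g_mat,
            "f_pedigree": fres.f,
        }
    )
    truth["liability"] = np.nan
    truth.loc[truth["animal"].isin(fams.index), "liability"] = (
        pd.Series(liab - thresh, index=fams.index).reindex(
            truth.loc[truth["animal"].isin(fams.index), "animal"]
        ).to_numpy()
    )
    qtl = pd.DataFrame(
        {
            "snp": genotypes.snp_map["snp"].to_numpy()[qtl_idx],
            "chrom": genotypes.snp_map["chrom"].to_numpy()[qtl_idx],
            "pos": genotypes.snp_map["pos"].to_numpy()[qtl_idx],
            "snp_index": qtl_idx,
            "variance_fraction": fracs,
            "effect_length": alpha_len,
            "effect_maturation": alpha_mat_out,
        }
    )
    return PhenotypeTable(animals, family_survival), truth, qtl


def simulate(config: SimConfig) -> SimOutput:
    """Pedigree, genotypes, phenotypes and truth in one call."""
    ped = simulate_pedigree(config)
    geno = gene_drop(ped, config)
    pheno, truth, qtl = simulate_phenotypes(ped, geno, config)
    return SimOutput(ped, geno, pheno, truth, qtl, final_generation_families(ped), config)
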