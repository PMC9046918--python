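"""Genotype matrix container, readers/writers and SNP/sample quality control.

The QC suite mirrors standard reduced-representation panel filtering for an
aquaculture breeding population:

* minor allele frequency below a floor (default 0.05);
* SNP call rate below a floor (default 0.30) in ANY population group;
* observed heterozygosity above a ceiling (default 0.70) — paralogue signal;
* absolute deviation of the observed from the expected heterozygote
  FRACTION above a ceiling (default 0.15) — Hardy-Weinberg departure on the
  frequency scale, so the rule is not sample-size dependent.

Removal reasons are assigned with exactly that precedence, one reason per
SNP.  Sample filtering (call rate, default floor 0.70, boundary kept at >=)
runs after SNP filtering, i.e. animal call rates are computed on the
filtered panel.  Allele frequencies are not recomputed between the two
passes of a single call; missing genotypes stay missing through QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "FilterReport",
    "compute_snp_stats",
    "filter_snps",
    "filter_samples",
    "read_tsv",
    "read_vcf",
    "read_ped_map",
    "write_tsv",
    "write_vcf",
]


@dataclass
class GenotypeMatrix:
    """Animals x biallelic SNPs coded 0/1/2 (NaN = missing) with a SNP map."""

    animal_ids: np.ndarray            # str, length n
    snp_map: pd.DataFrame             # columns snp, chrom, pos (map order = column order)
    calls: np.ndarray                 # float (n, m), values {0,1,2,NaN}
    populations: np.ndarray | None = None   # per-animal group label
    families: np.ndarray | None = None      # optional per-animal full-sib family

    def __post_init__(self):
        n, m = self.calls.shape
        if len(self.animal_ids) != n:
            raise ValueError("animal_ids length does not match call matrix")
        if len(self.snp_map) != m:
            raise ValueError("snp_map length does not match call matrix")
        if (self.snp_map["pos"] < 0).any():
            raise ValueError("negative SNP position")
        if self.populations is None:
            self.populations = np.array(["pop1"] * n, dtype=object)

    @property
    def n_animals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def take_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            snp_map=self.snp_map.loc[mask].reset_index(drop=True),
            calls=self.calls[:, np.asarray(mask, bool)],
        )

    def take_animals(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, bool)
        return replace(
            self,
            animal_ids=self.animal_ids[mask],
            calls=self.calls[mask],
            populations=None if self.populations is None else self.populations[mask],
            families=None if self.families is None else self.families[mask],
        )


@dataclass
class FilterReport:
    """Per-SNP / per-animal keep-or-remove decisions with one reason each."""

    snp_status: pd.DataFrame = field(default_factory=pd.DataFrame)     # snp, kept, reason
    sample_status: pd.DataFrame = field(default_factory=pd.DataFrame)  # animal, kept, reason
    counts: dict = field(default_factory=dict)

    def to_tsv(self, snp_path=None, sample_path=None) -> None:
        if snp_path is not None and len(self.snp_status):
            self.snp_status.to_csv(snp_path, sep="\t", index=False)
        if sample_path is not None and len(self.sample_status):
            self.sample_status.to_csv(sample_path, sep="\t", index=False)


def compute_snp_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP allele frequency, MAF, call rates, observed and expected het.

    Expected heterozygosity is the plain 2p(1-p) from non-missing calls.  A
    SNP with every call missing gets NaN stats and ``all_missing=True``.
    """
    calls = g.calls
    nonmiss = ~np.isnan(calls)
    n_called = nonmiss.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(calls, axis=0) / 2.0
        ho = np.nansum(calls == 1, axis=0) / np.where(n_called > 0, n_called, 1)
    ho = np.where(n_called > 0, ho, np.nan)
    he = 2.0 * p * (1.0 - p)
    maf = np.minimum(p, 1.0 - p)
    stats = pd.DataFrame(
        {
            "snp": g.snp_map["snp"].to_numpy(),
            "freq": p,
            "maf": maf,
            "call_rate": n_called / g.n_animals,
            "ho": ho,
            "he": he,
            "all_missing": n_called == 0,
        }
    )
    for pop in pd.unique(g.populations):
        sel = g.populations == pop
        stats[f"call_rate_{pop}"] = nonmiss[sel].sum(axis=0) / max(int(sel.sum()), 1)
    pop_cols = [c for c in stats.columns if c.startswith("call_rate_")]
    stats["min_pop_call_rate"] = stats[pop_cols].min(axis=1)
    return stats


def filter_snps(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    min_pop_call_rate: float = 0.30,
    max_het: float = 0.70,
    hwe_dev_max: float = 0.15,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the SNP filters; reasons in precedence maf > call_rate > het_excess > hwe_dev."""
    stats = compute_snp_stats(g)
    reason = np.array([""] * g.n_snps, dtype=object)
    maf_fail = (stats["maf"] < maf_min).to_numpy() | stats["all_missing"].to_numpy()
    cr_fail = (stats["min_pop_call_rate"] < min_pop_call_rate).to_numpy()
    het_fail = (stats["ho"] > max_het).to_numpy()
    hwe_fail = (np.abs(stats["ho"] - stats["he"]) > hwe_dev_max).to_numpy()
    reason[hwe_fail] = "hwe_dev"
    reason[het_fail] = "het_excess"
    reason[cr_fail] = "call_rate"
    reason[maf_fail] = "maf"
    kept = reason == ""
    report = FilterReport(
        snp_status=pd.DataFrame(
            {"snp": stats["snp"], "kept": kept, "reason": np.where(kept, "", reason)}
        ),
        counts={
            "snps_in": g.n_snps,
            "snps_kept": int(kept.sum()),
            **{
                r: int((reason == r).sum())
                for r in ("maf", "call_rate", "het_excess", "hwe_dev")
            },
        },
    )
    out = g.take_snps(kept)
    if out.n_snps == 0:
        warnings.warn("all SNPs removed by QC thresholds")
    return out, report


def filter_samples(g: GenotypeMatrix, min_call_rate: float = 0.70) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove animals whose fraction of non-missing calls is below the floor.

    The boundary is kept: an animal typed at exactly the floor stays.
    """
    if g.n_snps == 0:
        cr = np.ones(g.n_animals)
    else:
        cr = (~np.isnan(g.calls)).sum(axis=1) / g.n_snps
    kept = cr >= min_call_rate
    report = FilterReport(
        sample_status=pd.DataFrame(
            {
                "animal": g.animal_ids,
                "call_rate": cr,
                "kept": kept,
                "reason": np.where(kept, "", "call_rate"),
            }
        ),
        counts={
            "animals_in": g.n_animals,
            "animals_kept": int(kept.sum()),
            "call_rate": int((~kept).sum()),
        },
    )
    return g.take_animals(kept), report


# ---------------------------------------------------------------------------
# readers / writers

_MISSING_TOKENS = {"NA", "nan", ".", ""}


def read_tsv(path, populations=None, families=None) -> GenotypeMatrix:
    """Plain matrix dialect: first column animal id, one column per SNP (0/1/2/NA).

    SNP columns named ``chrom:pos`` or ``chrom:pos:id`` carry their own map;
    otherwise all SNPs land on chromosome "un" at consecutive positions.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    animal_ids = df.iloc[:, 0].to_numpy(dtype=object)
    snp_cols = df.columns[1:]
    chroms, poss, snps = [], [], []
    for i, c in enumerate(snp_cols):
        parts = c.split(":")
        if len(parts) >= 2 and parts[1].isdigit():
            chroms.append(parts[0]); poss.append(int(parts[1]))
            snps.append(parts[2] if len(parts) > 2 else c)
        else:
            chroms.append("un"); poss.append(i + 1); snps.append(c)
    calls = df.iloc[:, 1:].replace(list(_MISSING_TOKENS), np.nan).astype(float).to_numpy()
    return GenotypeMatrix(
        animal_ids,
        pd.DataFrame({"snp": snps, "chrom": chroms, "pos": poss}),
        calls,
        populations=None if populations is None else np.asarray(populations, object),
        families=None if families is None else np.asarray(families, object),
    )


def write_tsv(g: GenotypeMatrix, path) -> None:
    cols = [
        f"{c}:{p}:{s}"
        for c, p, s in zip(g.snp_map["chrom"], g.snp_map["pos"], g.snp_map["snp"])
    ]
    df = pd.DataFrame(g.calls, columns=cols)
    df.insert(0, "animal", g.animal_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.0f")


def read_vcf(path, populations=None) -> GenotypeMatrix:
    """Biallelic VCF records via cyvcf2; GT parsed to alt-allele dosage."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animal_ids = np.array(vcf.samples, dtype=object)
    chroms, poss, snps, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        snps.append(var.ID or f"{var.CHROM}:{var.POS}")
        gt = var.gt_types.astype(float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        dosage = np.where(gt == 3, 2.0, gt)
        dosage[gt == 2] = np.nan
        rows.append(dosage)
    vcf.close()
    calls = np.array(rows).T if rows else np.empty((len(animal_ids), 0))
    return GenotypeMatrix(
        animal_ids,
        pd.DataFrame({"snp": snps, "chrom": chroms, "pos": poss}),
        calls,
        populations=None if populations is None else np.asarray(populations, object),
    )


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Minimal biallelic VCF with GT only (A/B placeholder alleles)."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(g.snp_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, g.animal_ids)) + "\n")
        for j in range(g.n_snps):
            row = g.snp_map.iloc[j]
            gts = "\t".join(
                "./." if np.isnan(v) else code[v] for v in g.calls[:, j]
            )
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp']}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_ped_map(ped_path, map_path, populations=None) -> GenotypeMatrix:
    """PLINK-style text .ped/.map, genotypes converted to 0/1/2.

    The counted allele per SNP is the first non-missing allele encountered;
    '0' denotes a missing allele call.
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "snp", "cm", "pos"], dtype=str)
    m = len(mp)
    ids, rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[1])
            alleles = parts[6 : 6 + 2 * m]
            rows.append(alleles)
    counted = [None] * m
    calls = np.full((len(ids), m), np.nan)
    for i, alleles in enumerate(rows):
        for j in range(m):
            a, b = alleles[2 * j], alleles[2 * j + 1]
            if a == "0" or b == "0":
                continue
            if counted[j] is None:
                counted[j] = a
            calls[i, j] = (a == counted[j]) + (b == counted[j])
    return GenotypeMatrix(
        np.array(ids, dtype=object),
        pd.DataFrame({"snp": mp["snp"], "chrom": mp["chrom"], "pos": mp["pos"].astype(int)}),
        calls,
        populations=None if populations is None else np.asarray(populations, object),
    )
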