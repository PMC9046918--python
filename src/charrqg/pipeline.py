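"""End-to-end orchestration: simulate/load -> QC -> diversity -> pedigree ->
threshold-model heritability -> WssGBLUP GWAS, with persisted artifacts.

Every stage is a pure function of (inputs, config, seed); a single global
seed fans out to per-stage seeds through a stable CRC32 derivation, so
stages rerun independently yet reproducibly.  All tabular outputs are TSV
with headers; the run report collects per-stage record counts and headline
results.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import diversity as divmod_
from . import genoqc, relmat, synthdata
from .models import GibbsConfig, ModelSpec, threshold_gibbs_genomic
from .pedigree import inbreeding, sort_pedigree
from .wssgwas import wssgblup_iterate

__all__ = ["RunConfig", "run_full", "stage_seed", "cli"]

EXIT_CONFIG, EXIT_DATA, EXIT_NOCONV = 2, 3, 4


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything a full run needs; defaults give a desk-scale study."""

    seed: int = 0
    sim: dict = field(default_factory=dict)            # SimConfig overrides
    qc: dict = field(default_factory=dict)             # thresholds
    sample_call_rate: float = 0.70
    exclude_groups: tuple = ()                         # groups left out of Fst/PCA
    pca_k: int = 10
    h2_length: float = 0.30
    maturation_chain: dict = field(
        default_factory=lambda: {"iterations": 20_000, "burn_in": 4_000, "thin": 10}
    )
    gwas_trait: str = "length_t3"
    gwas_max_iter: int = 3
    gwas_window: int = 10
    out_dir: str = "results/run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise synthdata.ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


def _write(df: pd.DataFrame, path: Path, descriptions: dict | None = None):
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    if descriptions:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(descriptions, indent=2)
        )


def run_full(config: RunConfig) -> dict:
    """Execute every stage in study order and return the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}}

    def record(stage, t0, **info):
        report["stages"][stage] = {"seconds": round(time.time() - t0, 2), **info}

    # --- simulate -----------------------------------------------------------
    t0 = time.time()
    sim_cfg = synthdata.SimConfig(
        **{"seed": stage_seed(config.seed, "simulate"), **config.sim}
    )
    sim = synthdata.simulate(sim_cfg)
    sim.pedigree.to_csv(out / "pedigree.csv")
    genoqc.write_tsv(sim.genotypes, out / "genotypes.tsv")
    sim.phenotypes.animals.to_csv(out / "phenotypes.csv", index=False)
    sim.phenotypes.family_survival.to_csv(out / "family_survival.csv", index=False)
    _write(sim.true_values, out / "truth.tsv")
    record("simulate", t0, animals=sim.pedigree.n, snps=sim.genotypes.n_snps)

    # --- QC -----------------------------------------------------------------
    t0 = time.time()
    g1, snp_rep = genoqc.filter_snps(sim.genotypes, **config.qc)
    g2, samp_rep = genoqc.filter_samples(g1, config.sample_call_rate)
    snp_rep.to_tsv(snp_path=out / "qc_snps.tsv")
    samp_rep.to_tsv(sample_path=out / "qc_samples.tsv")
    record(
        "qc", t0,
        **{f"snp_{k}": v for k, v in snp_rep.counts.items()},
        **{f"sample_{k}": v for k, v in samp_rep.counts.items()},
    )

    # --- diversity ----------------------------------------------------------
    t0 = time.time()
    pops = divmod_.group_heterozygosity(g2, "population")
    final_label = f"YC{sim.pedigree.year.max()}"
    exclude = tuple(config.exclude_groups) or (final_label,)
    fst = divmod_.pairwise_fst(g2, "population", exclude=exclude)
    pca = divmod_.genotype_pca(
        g2, k=min(config.pca_k, g2.n_animals - 1), exclude_groups=exclude
    )
    has_fam = g2.families is not None
    fam_mask = (
        np.array([f is not None and f == f for f in g2.families])
        if has_fam
        else np.zeros(g2.n_animals, bool)
    )
    fam_div = divmod_.group_heterozygosity(g2.take_animals(fam_mask), "family")
    _write(pops, out / "diversity_populations.tsv")
    fst.to_csv(out / "fst.tsv", sep="\t")
    _write(pca.to_frame(), out / "pca_scores.tsv")
    _write(fam_div, out / "diversity_families.tsv")
    record("diversity", t0, groups=len(pops), families=len(fam_div))

    # --- pedigree inbreeding ------------------------------------------------
    t0 = time.time()
    ped = sort_pedigree(sim.pedigree)
    fres = inbreeding(ped)
    fam_f = fres.family_means(sim.families)
    _write(fres.as_series().reset_index().rename(columns={"index": "animal"}),
           out / "inbreeding.tsv")
    _write(fam_f.reset_index().rename(columns={"index": "family"}),
           out / "family_inbreeding.tsv")
    surv = sim.phenotypes.family_survival.set_index("family")["survival"]
    corrs = divmod_.family_correlations(fam_div, fam_f, surv)
    _write(corrs, out / "family_correlations.tsv")
    record("pedigree", t0, mean_f=float(fres.f[ped.year == ped.year.max()].mean()))

    # --- threshold-model heritability (genomic animal effects) -------------
    t0 = time.time()
    chain = GibbsConfig(
        **config.maturation_chain, seed=stage_seed(config.seed, "maturation")
    )
    spec = ModelSpec(
        response="maturation",
        fixed_effects=["length_t3", "tank"],
        link="probit",
        h2=0.28,
    )
    freqs = relmat.allele_frequencies(g2.calls)
    poly = (freqs > 0) & (freqs < 1)
    z = relmat.centred_genotypes(g2.calls[:, poly], freqs[poly])
    post, _sols = threshold_gibbs_genomic(
        sim.phenotypes.animals, spec, z, g2.animal_ids, chain
    )
    lo, hi = post.h2_hpd()
    _write(post.to_frame(), out / "maturation_chain.tsv")
    record("maturation_h2", t0, h2_mean=post.h2_mean, hpd_low=lo, hpd_high=hi)

    # --- WssGBLUP GWAS ------------------------------------------------------
    t0 = time.time()
    gwas_spec = ModelSpec(
        response=config.gwas_trait,
        fixed_effects=["tank", "sex"],
        h2=config.h2_length,
    )
    states = wssgblup_iterate(
        sim.phenotypes.animals, gwas_spec, ped, g2,
        max_iter=config.gwas_max_iter, window_size=config.gwas_window,
    )
    last = states[-1]
    _write(last.windows.sort_values("pct_var", ascending=False),
           out / "gwas_windows.tsv")
    _write(last.snp_table, out / "gwas_snps.tsv")
    _write(
        pd.DataFrame(
            {"iteration": [s.iteration for s in states],
             "C": [s.convergence for s in states]}
        ),
        out / "gwas_convergence.tsv",
    )
    top = last.windows.nlargest(1, "pct_var").iloc[0]
    record(
        "gwas", t0,
        iterations=len(states),
        top_window_chrom=str(top["chrom"]),
        top_window_pct=float(top["pct_var"]),
        windows_gt1pct=int((last.windows["pct_var"] > 1.0).sum()),
    )

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


# ---------------------------------------------------------------------------
# command-line interface


@click.group()
def cli():
    """Breeding-programme genetics toolkit (synthetic study driver)."""


def _load_config(path) -> RunConfig:
    return RunConfig.from_yaml(path) if path else RunConfig()


@cli.command("run-all")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "out_dir", default=None)
def run_all_cmd(config_path, out_dir):
    """Full study: simulate, QC, diversity, inbreeding, h2, GWAS."""
    try:
        cfg = _load_config(config_path)
        if out_dir:
            cfg.out_dir = out_dir
        report = run_full(cfg)
    except synthdata.ConfigError as exc:
        raise SystemExit(EXIT_CONFIG) from exc
    except (ValueError, KeyError) as exc:
        click.echo(f"data error: {exc}", err=True)
        raise SystemExit(EXIT_DATA) from exc
    for stage, info in report["stages"].items():
        click.echo(f"{stage}: {info}")


@cli.command("simulate")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "out_dir", default="results/sim")
def simulate_cmd(config_path, out_dir):
    """Write synthetic pedigree/genotypes/phenotypes to a directory."""
    try:
        cfg = _load_config(config_path)
        sim_cfg = synthdata.SimConfig(
            **{"seed": stage_seed(cfg.seed, "simulate"), **cfg.sim}
        )
        sim = synthdata.simulate(sim_cfg)
    except synthdata.ConfigError as exc:
        click.echo(f"config error: {exc}", err=True)
        raise SystemExit(EXIT_CONFIG) from exc
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim.pedigree.to_csv(out / "pedigree.csv")
    genoqc.write_tsv(sim.genotypes, out / "genotypes.tsv")
    genoqc.write_vcf(sim.genotypes, out / "genotypes.vcf")
    sim.phenotypes.animals.to_csv(out / "phenotypes.csv", index=False)
    sim.phenotypes.family_survival.to_csv(out / "family_survival.csv", index=False)
    sim.true_values.to_csv(out / "truth.tsv", sep="\t", index=False)
    click.echo(f"wrote {sim.pedigree.n} animals x {sim.genotypes.n_snps} SNPs to {out}")


@cli.command("qc")
@click.option("--in", "in_path", required=True, type=click.Path(exists=True))
@click.option("--format", "fmt", type=click.Choice(["vcf", "tsv"]), default="tsv")
@click.option("--maf", default=0.05)
@click.option("--pop-call-rate", default=0.30)
@click.option("--max-het", default=0.70)
@click.option("--hwe-dev", default=0.15)
@click.option("--sample-call-rate", default=0.70)
@click.option("--out", "out_dir", default="results/qc")
def qc_cmd(in_path, fmt, maf, pop_call_rate, max_het, hwe_dev, sample_call_rate, out_dir):
    """SNP and sample quality control on a genotype file."""
    g = genoqc.read_vcf(in_path) if fmt == "vcf" else genoqc.read_tsv(in_path)
    g1, snp_rep = genoqc.filter_snps(g, maf, pop_call_rate, max_het, hwe_dev)
    g2, samp_rep = genoqc.filter_samples(g1, sample_call_rate)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genoqc.write_tsv(g2, out / "filtered.tsv")
    snp_rep.to_tsv(snp_path=out / "qc_snps.tsv")
    samp_rep.to_tsv(sample_path=out / "qc_samples.tsv")
    click.echo(json.dumps({**snp_rep.counts, **samp_rep.counts}))
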