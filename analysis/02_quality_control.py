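"""SNP and sample quality control of the simulated panel.

Applies the panel filters in their reporting order — minor allele frequency
< 0.05, call rate < 0.30 in any population group, observed heterozygosity
> 0.70, heterozygote-fraction deviation from Hardy-Weinberg expectation
> 0.15 — then removes animals typed for fewer than 70% of the retained SNPs.
"""

import importlib
from pathlib import Path

import pandas as pd

from charrqg.genoqc import filter_samples, filter_snps

step01 = importlib.import_module("01_simulate_breeding_program")
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sim = step01.study_sim()
    g1, snp_rep = filter_snps(sim.genotypes)
    g2, samp_rep = filter_samples(g1)
    print(f"SNPs: {snp_rep.counts['snps_in']} in, {snp_rep.counts['snps_kept']} kept "
          f"({snp_rep.counts['snps_kept'] / snp_rep.counts['snps_in'] * 100:.1f}%)")
    for reason in ("maf", "call_rate", "het_excess", "hwe_dev"):
        print(f"  removed for {reason}: {snp_rep.counts[reason]}")
    print(f"animals: {samp_rep.counts['animals_in']} in, "
          f"{samp_rep.counts['animals_kept']} kept "
          f"({samp_rep.counts['call_rate']} below 70% call rate)")
    pd.DataFrame([snp_rep.counts | samp_rep.counts]).to_csv(
        RESULTS / "02_qc_counts.tsv", sep="\t", index=False)
    snp_rep.snp_status.query("~kept").to_csv(
        RESULTS / "02_removed_snps.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
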