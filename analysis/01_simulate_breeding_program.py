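"""Simulate the breeding-programme study population.

Generates the synthetic nucleus the whole analysis runs on: a 44-family
final year class (sizes 27-63) with pedigree inbreeding spanning ~0.03-0.25,
a ~3,000-SNP panel over 39 chromosomes plus unplaced contigs, three
correlated length recordings (h2 = 0.30), binary maturation on the liability
scale (h2 = 0.28) and family-level eyed-stage survival.  Small summary
tables go to results/; the bulky genotype matrix is rewritten on the fly by
later steps (the simulation is deterministic in the seed), so nothing large
is persisted.
"""

from pathlib import Path

import numpy as np

from charrqg import synthdata
from charrqg.pedigree import inbreeding, sort_pedigree

SEED = 20260923
RESULTS = Path(__file__).resolve().parents[1] / "results"


def study_sim() -> synthdata.SimOutput:
    cfg = synthdata.SimConfig(seed=SEED, n_snps=3000, n_qtl=1,
                              qtl_variance_fractions=(0.20,))
    return synthdata.simulate(cfg)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    sim = study_sim()
    ped = sort_pedigree(sim.pedigree)
    fin = ped.year == ped.year.max()
    f = inbreeding(ped).f

    sizes = sim.families.value_counts()
    print(f"pedigree: {ped.n} animals over {ped.year.max() + 1} year classes")
    print(f"final year class: {int(fin.sum())} animals in {sizes.size} full-sib "
          f"families (sizes {sizes.min()}-{sizes.max()})")
    print(f"final-generation inbreeding: mean {f[fin].mean():.3f}, "
          f"range {f[fin].min():.3f}-{f[fin].max():.3f}")
    print(f"panel: {sim.genotypes.n_snps} SNPs, "
          f"{np.isnan(sim.genotypes.calls).mean() * 100:.1f}% missing calls")
    im = sim.phenotypes.animals["maturation"].mean()
    print(f"phenotypes: {len(sim.phenotypes.animals)} animals, "
          f"{im * 100:.1f}% immature at 2+ years")

    sizes.rename("n").rename_axis("family").reset_index().to_csv(
        RESULTS / "01_family_sizes.tsv", sep="\t", index=False)
    sim.qtl.to_csv(RESULTS / "01_planted_qtl.tsv", sep="\t", index=False)
    sim.phenotypes.family_survival.to_csv(
        RESULTS / "01_family_survival.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
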