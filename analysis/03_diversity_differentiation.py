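"""Heterozygosity, population differentiation and genotype PCA.

Reports mean observed/expected heterozygosity per year-class group and per
full-sib family, pairwise Weir-Cockerham Fst between the earlier year
classes (the large final cohort is excluded, as its sheer size would
dominate the comparison), and the leading principal components.
"""

import importlib
from pathlib import Path

import numpy as np

from charrqg.diversity import genotype_pca, group_heterozygosity, pairwise_fst
from charrqg.genoqc import filter_samples, filter_snps

step01 = importlib.import_module("01_simulate_breeding_program")
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sim = step01.study_sim()
    g, _ = filter_snps(sim.genotypes)
    g, _ = filter_samples(g)
    final_label = f"YC{max(int(p[2:]) for p in set(g.populations))}"

    pops = group_heterozygosity(g, "population")
    print("per-group heterozygosity:")
    print(pops.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    fst = pairwise_fst(g, "population", exclude=(final_label,))
    off = fst.to_numpy()[~np.eye(len(fst), dtype=bool)]
    print(f"pairwise Fst among earlier year classes: "
          f"{off.min():.4f}-{off.max():.4f}")

    pca = genotype_pca(g, k=5, exclude_groups=(final_label,))
    print("PCA variance fractions:",
          " ".join(f"{v * 100:.1f}%" for v in pca.var_frac))

    fam_mask = np.array([x == x and x is not None for x in g.families])
    fam = group_heterozygosity(g.take_animals(fam_mask), "family")
    print(f"family mean Ho: {fam['ho'].mean():.3f} "
          f"(range {fam['ho'].min():.3f}-{fam['ho'].max():.3f} "
          f"over {len(fam)} families)")

    pops.to_csv(RESULTS / "03_heterozygosity_groups.tsv", sep="\t", index=False)
    fst.to_csv(RESULTS / "03_fst.tsv", sep="\t")
    fam.to_csv(RESULTS / "03_heterozygosity_families.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
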