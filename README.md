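# charrqg

Quantitative and population genetics of a selectively bred Arctic charr
(*Salvelinus alpinus*) breeding programme: SNP and sample quality control,
genetic diversity and differentiation, pedigree inbreeding, liability-scale
heritability of sexual maturation, and weighted single-step GBLUP
(WssGBLUP) genome-wide association — packaged as a tested library with a
set of numbered analysis drivers.

Arctic charr farming rests on young breeding programmes in which a few
dozen full-sib families carry each year class, so diversity management
(inbreeding, family heterozygosity, embryo survival) and genetic evaluation
(growth, early maturation) have to be run from the same reduced-
representation SNP panel and pedigree.  The hatchery data this workflow was
designed around are public only as raw sequencing reads, so the package
includes a first-class synthetic breeding-programme generator
(`charrqg.synthdata`) that reproduces the study's structure — 44 full-sib
families of 27–63 sibs, pedigree inbreeding spanning ~0.03–0.25 with mean
~0.07, a few-thousand-SNP panel over 39 chromosomes plus unplaced contigs,
three correlated length recordings with h² ≈ 0.30, and binary maturation
with liability h² ≈ 0.28 — and every analysis, test and acceptance run
operates end-to-end on it.

## Core models

**Threshold (probit liability) animal model.** Maturation status
(0 = mature, 1 = non-mature at 2+ years) is modelled as y = I(l > 0) with
liability l = **Xb** + **Zu** + **e**, u ~ N(0, **G**σ²g), e ~ N(0, **I**);
the residual liability variance is fixed to 1 for identifiability and
h² = σ²g/(σ²g + 1).  Variance components are drawn by Gibbs sampling
(numba-compiled, noncentered parameterisation, prior uniform on h²), with
the posterior summarised by its mean and 95% highest-posterior-density
interval.

**Genomic relationships and single-step evaluation.**
**G** = **ZDZ**′ / 2Σpᵢ(1−pᵢ) (VanRaden) with SNP-weight matrix **D**;
G is tuned and blended against the pedigree block A₂₂ and combined with
the sparse pedigree inverse into
**H**⁻¹ = **A**⁻¹ + [0 0; 0 τ**G**\*⁻¹ − ω**A₂₂**⁻¹].

**WssGBLUP.** Iterate: solve the mixed-model equations for GEBVs û;
back-solve SNP effects â = q**DZ**′(**G**\*)⁻¹û; reweight with VanRaden's
nonlinearA dᵢ = 1.125^(|âᵢ|/sd(â) − 2); normalise so Σdᵢ equals the SNP
count; rebuild **G**; stop when C = Σ(wₜ−wₜ₋₁)²/Σwₜ² < 10⁻¹⁴.  The share of
additive genetic variance per nonoverlapping 10-SNP window is
var(Σzᵢâᵢ)/σ²g × 100.

**Diversity.** Observed/expected heterozygosity per group and full-sib
family, pairwise Weir–Cockerham Fst (ratio-of-sums across loci), genotype
PCA, recursive pedigree inbreeding F, and Pearson correlations of family
Ho, F and eyed-stage survival.

## Worked example

```python
from charrqg import synthdata, relmat
from charrqg.genoqc import filter_snps, filter_samples
from charrqg.models import ModelSpec, GibbsConfig, threshold_gibbs_genomic
from charrqg.wssgwas import wssgblup_iterate

sim = synthdata.simulate(synthdata.SimConfig(seed=20260923, n_snps=3000,
                                             n_qtl=1,
                                             qtl_variance_fractions=(0.20,)))
g, snp_report = filter_snps(sim.genotypes)      # MAF/call-rate/het/HWE rules
g, _ = filter_samples(g)                        # animals < 70% call rate

freqs = relmat.allele_frequencies(g.calls)
keep = (freqs > 0) & (freqs < 1)
z = relmat.centred_genotypes(g.calls[:, keep], freqs[keep])
spec = ModelSpec(response="maturation", fixed_effects=["length_t3", "tank"],
                 link="probit", h2=0.28)
post, _ = threshold_gibbs_genomic(sim.phenotypes.animals, spec, z,
                                  g.animal_ids, GibbsConfig(50_000, 10_000, 10))
print(f"h2 = {post.h2_mean:.2f}, 95% HPD {post.h2_hpd()}")

gwas = wssgblup_iterate(sim.phenotypes.animals,
                        ModelSpec(response="length_t3",
                                  fixed_effects=["tank", "sex"], h2=0.30),
                        sim.pedigree, sim.genotypes, max_iter=2)
print(gwas[-1].windows.nlargest(3, "pct_var")[["chrom", "window", "pct_var"]])
```

On this seed the run prints

```
h2 = 0.36, 95% HPD (0.2275..., 0.4936...)
     chrom  window   pct_var
3    chr01       3  0.414854
197  chr31       4  0.188867
238  chr38       0  0.148184
```

The generator's true liability heritability is 0.28, inside the 95% HPD;
a binary trait at ~1,900 records pins the liability variance only loosely,
and posterior means scatter about ±0.1 around truth across replicate
simulations (see `docs/methods.md`).  The window table puts the planted
QTL's 10-SNP window (chr01, window 3) first genome-wide, at roughly double
its unweighted share from iteration 1 — the sharpening the nonlinearA
weights exist for — while the remaining windows carry the polygenic
background at ≤0.2% each.

The same study, stage by stage with printed narration, lives in
`analysis/01_simulate_breeding_program.py` … `analysis/06_wssgblup_gwas.py`
(run them from the `analysis/` directory; summary tables land in
`results/`).  A single-command version with persisted artifacts:
`charrqg run-all --config run.yaml --out results/run`.

## Layout

- `src/charrqg/` — the library: `synthdata`, `genoqc`, `diversity`,
  `pedigree`, `relmat`, `models`, `wssgwas`, `pipeline`.
- `analysis/` — numbered drivers that narrate the study on the synthetic
  population.
- `tests/` — unit, property and end-to-end recovery tests.
- `docs/methods.md` — models, generator design, numerical choices and
  limitations.
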