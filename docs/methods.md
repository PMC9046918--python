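# Methods

`charrqg` reimplements, as a tested library plus a set of analysis drivers,
the complete post-genotyping workflow of a selectively bred Arctic charr
(*Salvelinus alpinus*) programme: SNP and sample quality control, genetic
diversity and differentiation, pedigree inbreeding, threshold-model
heritability of sexual maturation, and a weighted single-step GBLUP
(WssGBLUP) genome scan.  Because the original hatchery data exist publicly
only as raw sequencing reads, every analysis here runs on a synthetic
breeding programme whose statistical structure mirrors the study
population; this note records the models, the generator, the numerical
choices, and what the synthetic results do and do not demonstrate.

## The synthetic breeding programme

`synthdata.SimConfig` fixes the study conditions; the defaults are the
conditions used throughout the tests and the acceptance script.

**Pedigree.** Founders (default 60) are unrelated.  Two intermediate
generations mate with deliberate sire reuse, so the parental pool contains
full sibs, half sibs and cousins.  The final year class holds exactly
`n_families` full-sib families (default 44) with sizes uniform on 27–63.
Parent pairs for the final generation are chosen by matching per-family
target inbreeding values — drawn from a beta law on [0, 0.25] with design
mean 0.07 — to the closest available parental kinship, with each parent
used at most three times.  This reproduces the intended spread of pedigree
inbreeding (final-generation F ranges roughly 0.0–0.25, mean 0.07 ± 0.02)
without hand-placing individual matings.

**Genotypes.** SNPs (default 5,000; 3,000 in the analysis drivers) are
assigned to 39 chromosomes plus ~21% on unplaced contigs.  Founder
haplotypes are drawn at linkage equilibrium from per-SNP allele frequencies
uniform on `maf_range`; descendants receive gametes under Haldane
recombination (no interference), 1 Morgan per chromosome (0.05 M per
contig).  Linkage disequilibrium therefore arises purely from
co-segregation within the pedigree — realistic for a closed nucleus, but
without the long-range background LD of a real population.  Missing calls
are masked uniformly at random (default 5%).

**Phenotypes.** The additive-genetic scale is standardised: a handful of
QTL plus a marker-realised polygenic background — small normal effects on
every remaining SNP.  A marker-realised background, rather than an abstract
pedigree polygenic term, makes the simulated genome behave the way the
single-step machinery assumes (all genetic variance is in principle
taggable by the panel) and is what makes window-based GWAS detection a fair
test.  QTL are drawn among common placed variants (founder frequency
0.15–0.85): a near-rare causal allele can lose half its variance to drift
through the parental bottleneck and is not a usable mapping target.  Both
trait families (length, maturation liability) use the same QTL positions
with independent effect draws, so genome scans of different traits can
share peaks.  Realised variances are calibrated per component over the
phenotyped cohort — each QTL's share, the background, and finally the
total — so realised heritability and QTL fractions match the configuration
exactly instead of drifting with the random effect draw.

Length at three time points (means 190/300/430 mm, SDs 23/30/42 mm) adds
tank effects (8 tanks, SD 15% of the trait SD), a male size advantage of
5%, and residuals correlated across time points so the phenotypic
correlations approximate the configured matrix (defaults 0.45–0.74).
Narrow-sense h² net of fixed effects defaults to 0.30.  Maturation
liability is the genetic value (variance h²/(1−h²) with h² = 0.28) plus a
standard-normal residual, thresholded at the sample quantile that yields
the configured maturity prevalence (default 76.5%; class coding 0 = mature,
1 = non-mature).  Family eyed-stage survival is beta-distributed (mean
0.75, concentration 15); `survival_association` couples it to family mean F
through a Gaussian copula, with 0 (the default) giving the null scenario.

**What passing tests show.** Recovery of h², inbreeding–diversity
correlations and QTL windows on this generator demonstrates that the
estimators are implemented correctly and behave as expected under the
study's family structure and sample sizes.  It does not validate the
upstream genotyping, the absence of genotyping artefacts correlated with
family, environmental maternal effects, or LD patterns beyond pedigree
co-segregation.

## Quality control

Per-SNP statistics use non-missing calls only: allele frequency p̂, MAF,
overall and per-population call rate, observed heterozygote fraction Ho,
expected heterozygosity He = 2p̂(1−p̂) (no small-sample correction by
default).  Filters, with one removal reason per SNP in this precedence:

1. MAF < 0.05 (an all-missing SNP is also flagged here);
2. call rate < 0.30 in *any* population group;
3. Ho > 0.70 (collapsed-paralogue signal);
4. |Ho − He| > 0.15 — a Hardy–Weinberg screen on the heterozygote
   *fraction* scale, so the threshold is not sample-size dependent.

Sample filtering (call rate < 0.70 removed; the boundary is kept) runs
after SNP filtering, on the filtered panel, and allele frequencies are not
recomputed between the two passes of one call.  Missing genotypes stay
missing through QC; downstream consumers decide imputation.

## Diversity and differentiation

Group Ho/He use within-group frequencies and complete observations per SNP.
Pairwise Fst is Weir & Cockerham's θ with the ratio-of-sums aggregation
Σa/Σ(a+b+c) over loci; loci with a zero total component for a pair are
skipped; small negative values are legitimate estimator behaviour.  PCA
operates on centred, optionally frequency-scaled genotypes with mean
imputation used only inside the decomposition; an over-represented group
(the final year class, by default, in the drivers) can be excluded.
Family-level associations (Ho vs F vs survival) are plain Pearson
correlations with n reported; zero-variance inputs yield NaN rather than
an arbitrary value.  On the generator, family mean Ho is almost entirely
determined by the parents' kinship, so corr(Ho, F) comes out strongly
negative (≈ −0.95 at a few thousand SNPs); moderate real-data values
reflect genotyping noise and family-specific founder diversity the
generator does not emulate.

## Pedigree algebra

`a_matrix` is Henderson's tabular method.  `inbreeding` computes
F(i) = kinship(sire, dam) by the classical recursion with memoisation,
never materialising A; on every tested pedigree it equals diag(A) − 1 to
1e−12.  Under the `year_mean` unknown-parent policy, an animal with both
parents unknown is assigned the running mean F of the preceding year class
(global running mean as fallback), and that F propagates through its
self-kinship; the policy never lowers any F below the classical value and
makes no claim of bit-compatibility with any legacy tool.  `a_inverse`
applies Henderson's rules with inbreeding,
d_i = 0.5 − 0.25(F_s + F_d) (one/no known parents: 0.75 − 0.25 F_known / 1).

## Relationship matrices and the single-step system

The genomic matrix is VanRaden's G = Z D Z′ / (2Σp_i(1−p_i)) with Z centred
by 2p_i (missing calls imputed to the centring value), allele frequencies
computed from the current genotyped set, monomorphic SNPs excluded with a
warning, and SNP weights D normalised to sum to the SNP count so the
implied total genetic variance is constant across reweighting iterations;
the denominator always uses unweighted 2Σp(1−p).  Mean-adjust tuning maps
G affinely so its mean diagonal and mean off-diagonal match A22, then
blending G* = 0.95·G_tuned + 0.05·A22 guarantees invertibility (centring by
sample frequencies alone leaves 1 in G's null space).  The single-step
inverse is H⁻¹ = A⁻¹ + [0 0; 0 τG*⁻¹ − ωA22⁻¹] with τ = ω = 1.

## Animal models

The linear model y = Xb + Zu + e is solved from Henderson's MME by dense
Cholesky with one step of iterative refinement; the relative residual of
the normal equations is reported (tests require < 1e−10).  Fixed effects
use treatment contrasts (first level dropped); any remaining confounded
columns are removed by pivoted QR and named in the output.  Variance
components are supplied (default length h² = 0.30); an optional Gibbs
sampler (`linear_gibbs`) estimates them for self-contained runs.

**Threshold model.** Binary maturation is modelled on a latent liability
with probit link, threshold 0, residual variance fixed to 1, and
h² = σg²/(σg² + 1).  Two implementation points deserve record:

*Prior.* As σg² → ∞ the threshold likelihood tends to a positive constant
(every sign pattern remains attainable), so a flat prior on σg² yields an
*improper* posterior — chains drift to h² ≈ 1.  This was verified against a
brute-force quadrature posterior on a founders × full-sib design.  The
default prior is therefore uniform on h², i.e. p(σg²) = (1+σg²)⁻², proper
and neutral on the reported scale.

*Sampler.* A centered single-site Gibbs sampler retains a near-absorbing
high-scale mode even under the proper prior: liabilities, animal effects
and the variance can drift upward together while staying locally
self-consistent, and the probability penalty against that region is
invisible to local moves.  The sampler therefore uses the noncentered
parameterisation u = s·v with v ~ N(0, A) and s = √σg²: v is pinned by a
fixed-scale prior, single-record animals get a blocked draw (liability
sampled with the animal effect integrated out), and s is updated as a
regression slope with a Metropolis correction to the prior.  Against the
quadrature oracle the sampler's posterior mean agrees to ~0.01 with an
effective sample size several hundred per 2,400 retained draws.  The
numba-compiled kernel runs a 50k-iteration chain over ~2,400 animals in
well under a minute; the analysis drivers use 50k/10k/10
(iterations/burn-in/thin) as the desk-scale default, and longer
field-scale settings are plain configuration.

The per-draw genetic variance is reported on the parametric scale
s²·Σⱼvar(zⱼ) for the genomic sampler: the realised variance of a drawn
genetic-value vector would add the posterior noise of weakly identified
marker directions and inflate the summary once the SNP count approaches
the record count.

A caution on precision: a binary trait at ~2,000 records carries limited
information about a liability-scale variance.  Replicate simulations at
the study design show posterior means scattering ±0.1 around the true h²,
and occasional replicates whose realised genomic structure makes the
apparent heritability land well above truth — confirmed on one such
replicate by an independent estimator (a linear model on the 0/1 response
with the same G, converted to the liability scale by the
Dempster–Lerner factor), which exceeded the threshold model's own
posterior mean.  The HPD intervals honestly reflect that uncertainty.

HPD intervals use the sorted-window (shortest-interval) method and require
at least 100 retained draws.

## Weighted single-step GWAS

The loop follows the standard iterative scheme: D = I; build G, tune/blend,
form H⁻¹; solve for GEBVs; back-solve SNP effects â = qDZ′(G*)⁻¹û over the
genotyped animals with q = 1/(2Σp(1−p)); nonlinearA weights
d_i = 1.125^(|â_i|/sd(â) − 2) with the ratio capped at 5 (and with the
absolute value made explicit — weights must be monotone in effect
magnitude); normalise; repeat until the weight-change statistic
C = Σ(w_t − w_{t−1})²/Σw_t² falls below 1e−14, up to `max_iter` (default 5;
C is recorded per iteration, and a C that fails to decrease for three
consecutive iterations stops the loop with a warning).  Window variance
uses nonoverlapping windows of 10 adjacent SNPs in map order, restarted at
every chromosome (contigs window among themselves): the sample variance
across genotyped animals of the window score Σz_ij â_j, divided by the
run's σg² input (not re-estimated per iteration), ×100.  Window percentages
are not forced to sum to 100 — windows covary under family LD.

## Pipeline and reproducibility

`pipeline.run_full` executes simulate → QC → diversity → pedigree →
threshold h² → GWAS, persisting every stage's tables as TSV and a JSON run
report with per-stage counts, timings and headline numbers.  One global
seed fans out to per-stage seeds via CRC32 of the stage name, so stages
rerun independently yet reproducibly; identical configuration and seed
reproduce all key results exactly.  The `charrqg` CLI exposes `simulate`,
`qc` and `run-all` (exit codes: 2 configuration error, 3 data error).

## Problem sizes

Unit tests run on compact populations (hundreds of animals, a few hundred
SNPs).  The end-to-end checks use the study-scale design — 44 families,
~2,000 phenotyped animals, 2,000–3,000 SNPs, 50k-iteration chains — sizes
chosen so the full suite and the acceptance script each complete on a
single desktop core in minutes.

## Known limitations

- Founder linkage equilibrium: no calibrated LD decay; window-GWAS
  resolution on real panels will differ.
- The threshold sampler's uniform-on-h² prior is not THRGIBBS1F90's
  default; at small sample sizes (hundreds of records) the prior visibly
  widens the posterior.
- Survival is family-level only; within-family survival variation and
  maternal effects are not modelled.
- No unknown-parent groups or metafounders; the `year_mean` policy is a
  pragmatic stand-in.
- The maturation model includes total length as a fixed covariate while
  length is itself analysed as a GWAS response; that mirrors the field
  practice this package follows, and the potential collider concern is
  noted rather than resolved.
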