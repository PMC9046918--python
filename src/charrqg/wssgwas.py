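"""Weighted single-step GBLUP genome-wide association.

The procedure iterates between a single-step evaluation and SNP-level
weights derived from back-solved marker effects:

1.  D = I, t = 1.
2.  Build G = Z D Z' / (2 sum p(1-p)), tune/blend against A22, form H^-1.
3.  Solve the MME for GEBVs u-hat.
4.  Back-solve SNP effects  a-hat = q D Z' (G*)^-1 u-hat,  q = 1/(2 sum p(1-p)),
    using the genotyped animals' GEBVs only.
5.  nonlinearA weights  d_i = 1.125^(|a-hat_i|/sd(a-hat) - 2), departures
    capped at 5 sd.
6.  Normalise weights so sum d_i = n_snps (total genetic variance constant).
7.  Rebuild G with the new D and iterate from 3 until the weight-change
    statistic C = sum (w_t - w_{t-1})^2 / sum w_t^2 falls below tolerance.

The share of additive genetic variance per nonoverlapping window of 10
adjacent SNPs is var_animals(sum_j z_ij a-hat_j) / sigma_g^2 * 100, windows
restarted at every chromosome (unplaced contigs window among themselves).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from . import relmat
from .genoqc import GenotypeMatrix
from .models import GibbsConfig, ModelSpec, solve_mme, threshold_gibbs
from .pedigree import Pedigree, a22 as a22_of, a_inverse, inbreeding
from .relmat import GrmSpec

__all__ = [
    "GwasState",
    "backsolve_snp_effects",
    "nonlinearA_weights",
    "convergence_stat",
    "window_variance",
    "wssgblup_iterate",
]


@dataclass
class GwasState:
    """Everything produced by one WssGBLUP iteration."""

    iteration: int
    weights: np.ndarray
    snp_effects: np.ndarray
    gebv: pd.Series
    convergence: float
    windows: pd.DataFrame
    snp_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def backsolve_snp_effects(
    u_hat: np.ndarray, z: np.ndarray, d: np.ndarray, g_star: np.ndarray,
    freqs: np.ndarray,
) -> np.ndarray:
    """SNP effects from genotyped animals' GEBVs: a = q D Z' (G*)^-1 u."""
    q = 1.0 / relmat.grm_denominator(freqs)
    try:
        ginv_u = sla.solve(g_star, u_hat, assume_a="pos")
    except sla.LinAlgError as exc:
        raise np.linalg.LinAlgError("G* is singular; was blending skipped?") from exc
    return q * d * (z.T @ ginv_u)


def nonlinearA_weights(ahat: np.ndarray, cap_sd: float = 5.0) -> np.ndarray:
    """VanRaden nonlinearA: d_i = 1.125^(|a_i|/sd(a) - 2), capped at cap_sd.

    Returned un-normalised; callers normalise to sum d = n_snps.  A flat
    effect vector (sd = 0) yields all-ones weights with a warning.
    """
    ahat = np.asarray(ahat, float)
    s = ahat.std()
    if s <= 1e-12 * max(1.0, float(np.abs(ahat).max())):
        warnings.warn("sd of SNP effects is zero; keeping unit weights")
        return np.ones(ahat.size)
    ratio = np.minimum(np.abs(ahat) / s, cap_sd)
    return 1.125 ** (ratio - 2.0)


def convergence_stat(w: np.ndarray, w_prev: np.ndarray) -> float:
    """C = sum (w_i - w_prev_i)^2 / sum w_i^2 between weight vectors."""
    w = np.asarray(w, float)
    w_prev = np.asarray(w_prev, float)
    if w.shape != w_prev.shape:
        raise ValueError("weight vectors differ in length")
    denom = float(np.sum(w**2))
    if denom == 0:
        raise ValueError("all-zero weight vector")
    return float(np.sum((w - w_prev) ** 2) / denom)


def window_variance(
    ahat: np.ndarray,
    z: np.ndarray,
    snp_map: pd.DataFrame,
    sigma_g: float,
    window_size: int = 10,
) -> pd.DataFrame:
    """Percent of additive genetic variance per window of adjacent SNPs.

    Per window the genetic score sum_j z_ij a_j is formed across genotyped
    animals and its sample variance divided by sigma_g^2.  Windows never
    span chromosomes; trailing windows may hold fewer SNPs.  SNPs are taken
    in map order (chromosome, then position).
    """
    if sigma_g <= 0:
        raise ValueError("sigma_g must be positive")
    order = np.lexsort((snp_map["pos"].to_numpy(), snp_map["chrom"].astype(str).to_numpy()))
    rows = []
    chrom_arr = snp_map["chrom"].to_numpy()
    pos_arr = snp_map["pos"].to_numpy()
    for chrom in pd.unique(chrom_arr[order]):
        idx = order[chrom_arr[order] == chrom]
        for w0 in range(0, idx.size, window_size):
            widx = idx[w0 : w0 + window_size]
            score = z[:, widx] @ ahat[widx]
            pct = float(np.var(score, ddof=1) / sigma_g * 100.0)
            rows.append(
                {
                    "chrom": chrom,
                    "window": w0 // window_size,
                    "start": int(pos_arr[widx].min()),
                    "end": int(pos_arr[widx].max()),
                    "n_snps": int(widx.size),
                    "pct_var": pct,
                    "snp_idx_first": int(widx[0]),
                    "snp_idx_last": int(widx[-1]),
                }
            )
    return pd.DataFrame(rows)


def wssgblup_iterate(
    phenotypes: pd.DataFrame,
    spec: ModelSpec,
    ped: Pedigree,
    genotypes: GenotypeMatrix,
    max_iter: int = 5,
    tol: float = 1e-14,
    window_size: int = 10,
    grm_spec: GrmSpec | None = None,
    chain: GibbsConfig | None = None,
) -> list[GwasState]:
    """Run the full weighted single-step GWAS loop; returns one state per iteration.

    The solver follows the model link: identity uses the direct MME solve,
    probit re-runs the threshold Gibbs sampler each iteration (GEBVs are the
    posterior means).  Iteration stops at C < tol, at ``max_iter``, or when C
    fails to decrease over three consecutive iterations (reported, not
    raised).
    """
    grm_spec = grm_spec or GrmSpec()
    geno_in_ped = set(ped.ids.tolist())
    if not set(genotypes.animal_ids.tolist()) <= geno_in_ped:
        raise KeyError("genotyped animals missing from the pedigree")
    geno_index = ped.index_of(genotypes.animal_ids)
    fres = inbreeding(ped)
    ainv = a_inverse(ped, fres)
    a22m = a22_of(ped, genotypes.animal_ids)
    sg, _se = spec.variance_components(
        phenotypes[spec.response].dropna().to_numpy(float)
    )

    # frequencies and Z are fixed across iterations; only D changes
    base_freqs = relmat.allele_frequencies(genotypes.calls)
    poly = (base_freqs > 0) & (base_freqs < 1)
    calls = genotypes.calls[:, poly]
    snp_map = genotypes.snp_map.loc[poly].reset_index(drop=True)
    freqs = base_freqs[poly]
    z = relmat.centred_genotypes(calls, freqs)
    m = z.shape[1]

    d = np.ones(m)
    states: list[GwasState] = []
    c_prev = np.inf
    rising = 0
    for t in range(1, max_iter + 1):
        g = (z * d[None, :]) @ z.T / relmat.grm_denominator(freqs)
        g = 0.5 * (g + g.T)
        g_star = relmat.blend_and_tune(g, a22m, grm_spec)
        hinv = relmat.h_inverse(
            ainv, a22m, g_star, geno_index, grm_spec.tau, grm_spec.omega
        )
        if spec.link == "probit":
            _post, sols = threshold_gibbs(
                phenotypes, spec, hinv, ped.ids, chain or GibbsConfig()
            )
        else:
            sols = solve_mme(phenotypes, spec, hinv, ped.ids)
        u_geno = sols.gebv.to_numpy()[geno_index]
        ahat = backsolve_snp_effects(u_geno, z, d, g_star, freqs)
        d_new = relmat.normalize_weights(nonlinearA_weights(ahat))
        c = convergence_stat(d_new, d)
        windows = window_variance(ahat, z, snp_map, sg, window_size)
        snp_table = pd.DataFrame(
            {
                "snp": snp_map["snp"],
                "chrom": snp_map["chrom"],
                "pos": snp_map["pos"],
                "effect": ahat,
                "weight": d,
                "abs_std_effect": np.abs(ahat) / ahat.std() if ahat.std() > 0 else 0.0,
            }
        )
        states.append(
            GwasState(t, d.copy(), ahat, sols.gebv, c, windows, snp_table)
        )
        if c < tol:
            break
        rising = rising + 1 if c >= c_prev else 0
        if rising >= 3:
            warnings.warn(f"weight-change statistic non-decreasing for 3 iterations (C={c:.3g})")
            break
        c_prev = c
        d = d_new
    return states
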