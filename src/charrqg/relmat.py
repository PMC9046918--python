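"""Genomic relationship matrices and the single-step H-inverse.

The genomic relationship matrix follows VanRaden's first method with an
optional diagonal SNP-weight matrix D:

    G = Z D Z' / (2 * sum_i p_i (1 - p_i))

where Z holds genotypes centred by twice the allele frequency.  The
denominator is always the unweighted 2*sum p(1-p); weights are normalised so
they sum to the number of SNPs, which keeps the implied total genetic
variance constant across reweighting iterations.

For single-step evaluations G is tuned to the pedigree relationships of the
genotyped animals (A22) and blended with a small proportion of A22 to
guarantee invertibility, then combined with the sparse pedigree inverse:

    H^-1 = A^-1 + [0 0; 0 tau*G*^-1 - omega*A22^-1]
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

__all__ = ["GrmSpec", "vanraden_grm", "blend_and_tune", "h_inverse", "grm_denominator"]


@dataclass
class GrmSpec:
    """Settings for building and conditioning the genomic matrix."""

    weights: np.ndarray | None = None     # per-SNP d_i, default all ones
    freqs: np.ndarray | None = None       # allele frequencies p_i, default from data
    blend_g: float = 0.95
    blend_a: float = 0.05
    tune: str = "mean_adjust"             # or "none"
    tau: float = 1.0
    omega: float = 1.0

    def __post_init__(self):
        if abs(self.blend_g + self.blend_a - 1.0) > 1e-12:
            raise ValueError("blend_g + blend_a must equal 1")
        if self.tune not in ("none", "mean_adjust"):
            raise ValueError(f"unknown tune mode {self.tune!r}")


def allele_frequencies(calls: np.ndarray) -> np.ndarray:
    """Counted-allele frequency per SNP from a 0/1/2 matrix with NaN missing."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(calls, axis=0) / 2.0


def centred_genotypes(calls: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Z = calls - 2p columnwise, missing calls imputed to 2p (i.e. 0 after centring)."""
    z = calls - 2.0 * freqs[None, :]
    return np.where(np.isnan(z), 0.0, z)


def grm_denominator(freqs: np.ndarray) -> float:
    return float(2.0 * np.sum(freqs * (1.0 - freqs)))


def vanraden_grm(
    calls: np.ndarray,
    spec: GrmSpec | None = None,
    return_parts: bool = False,
):
    """Weighted VanRaden G from a 0/1/2 call matrix (NaN = missing).

    Monomorphic SNPs (p in {0, 1}) carry no information and would leave the
    centred column identically zero; they are excluded from both numerator
    and denominator with a warning.

    With ``return_parts=True`` also returns (Z, freqs, kept_mask) for the
    retained SNPs, as needed by GWAS back-solving.
    """
    spec = spec or GrmSpec()
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    p = spec.freqs if spec.freqs is not None else allele_frequencies(calls)
    p = np.asarray(p, dtype=float)
    keep = (p > 0.0) & (p < 1.0)
    if not np.all(keep):
        warnings.warn(f"excluding {int((~keep).sum())} monomorphic SNPs from G")
    p = p[keep]
    z = centred_genotypes(calls[:, keep], p)
    d = np.ones(p.size) if spec.weights is None else np.asarray(spec.weights, float)[keep]
    if np.any(d < 0):
        raise ValueError("SNP weights must be non-negative")
    denom = grm_denominator(p)
    if denom <= 0:
        raise ValueError("degenerate panel: zero GRM denominator")
    g = (z * d[None, :]) @ z.T / denom
    g = 0.5 * (g + g.T)
    if return_parts:
        return g, z, p, keep
    return g


def normalize_weights(d: np.ndarray) -> np.ndarray:
    """Rescale weights so sum(d) equals the number of SNPs."""
    d = np.asarray(d, dtype=float)
    s = d.sum()
    if s <= 0:
        raise ValueError("weights sum to zero")
    return d * (d.size / s)


def blend_and_tune(g: np.ndarray, a22_mat: np.ndarray, spec: GrmSpec | None = None) -> np.ndarray:
    """Condition G on A22: mean-adjust scale/location, then blend.

    Tuning solves for (alpha, beta) so beta*G + alpha matches A22 in both
    mean diagonal and mean off-diagonal, then G* = blend_g*(beta G + alpha)
    + blend_a*A22.  With ``tune='none'`` and blend_a=0 this is the identity.
    """
    spec = spec or GrmSpec()
    g = np.asarray(g, float)
    if spec.tune == "mean_adjust":
        n = g.shape[0]
        off = ~np.eye(n, dtype=bool)
        gd, go = g.diagonal().mean(), g[off].mean()
        ad, ao = a22_mat.diagonal().mean(), a22_mat[off].mean()
        if abs(gd - go) < 1e-12:
            beta, alpha = 1.0, ad - gd
        else:
            beta = (ad - ao) / (gd - go)
            alpha = ad - beta * gd
        g = beta * g + alpha
    return spec.blend_g * g + spec.blend_a * np.asarray(a22_mat, float)


@dataclass
class HInverse:
    """Single-step inverse relationship matrix over all pedigree animals."""

    matrix: sp.csr_matrix
    geno_index: np.ndarray       # positions of genotyped animals in pedigree order
    tau: float = 1.0
    omega: float = 1.0

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def h_inverse(
    a_inv: sp.spmatrix,
    a22_mat: np.ndarray,
    g_star: np.ndarray,
    geno_index: np.ndarray,
    tau: float = 1.0,
    omega: float = 1.0,
) -> HInverse:
    """H^-1 = A^-1 + [0 0; 0 tau*G*^-1 - omega*A22^-1] on the genotyped block."""
    geno_index = np.asarray(geno_index, dtype=np.int64)
    n = a_inv.shape[0]
    if np.any(geno_index < 0) or np.any(geno_index >= n):
        raise IndexError("genotyped-animal index outside pedigree range")
    a = sp.coo_matrix(a_inv)
    if geno_index.size:
        k = geno_index.size
        block = np.zeros((k, k))
        if tau != 0.0:
            block += tau * _inv_psd(g_star)
        if omega != 0.0:
            block -= omega * _inv_psd(a22_mat)
        rows = np.concatenate([a.row, np.repeat(geno_index, k)])
        cols = np.concatenate([a.col, np.tile(geno_index, k)])
        vals = np.concatenate([a.data, block.ravel()])
        h = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    else:
        h = a.tocsr()
    return HInverse(h, geno_index, tau, omega)


def _inv_psd(m: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric positive-definite matrix via Cholesky."""
    m = np.asarray(m, float)
    try:
        c, low = sla.cho_factor(m, lower=True, check_finite=False)
    except sla.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "matrix not positive definite; was blending skipped?"
        ) from exc
    inv = sla.cho_solve((c, low), np.eye(m.shape[0]), check_finite=False)
    return 0.5 * (inv + inv.T)
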