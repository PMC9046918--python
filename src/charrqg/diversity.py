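"""Genetic-diversity metrics: heterozygosity, pairwise Fst, PCA, correlations.

Expected heterozygosity is the plain 2p(1-p) within the group (no
small-sample correction by default, matching common RAD-panel reporting; an
unbiased flag is available).  Pairwise Fst is the Weir & Cockerham (1984)
theta, aggregated across loci as the ratio of summed variance components
(sum a / sum (a+b+c)), the standard multi-locus estimator.  PCA operates on
mean-imputed, centred genotypes; diversity metrics themselves use complete
observations per SNP only.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .genoqc import GenotypeMatrix

__all__ = [
    "group_heterozygosity",
    "pairwise_fst",
    "fst_components",
    "genotype_pca",
    "family_correlations",
    "PcaResult",
]


def _labels(g: GenotypeMatrix, grouping) -> np.ndarray:
    if isinstance(grouping, str):
        if grouping == "population":
            return np.asarray(g.populations, object)
        if grouping == "family":
            if g.families is None:
                raise ValueError("genotype matrix carries no family labels")
            return np.asarray(g.families, object)
        raise ValueError(f"unknown grouping {grouping!r}")
    return np.asarray(grouping, object)


def group_heterozygosity(
    g: GenotypeMatrix, grouping="population", unbiased: bool = False
) -> pd.DataFrame:
    """Mean observed and expected heterozygosity per group.

    Ho averages, over SNPs with at least one call in the group, the
    heterozygote fraction; He averages 2p(1-p) with p estimated within the
    group.  ``unbiased=True`` applies the 2n/(2n-1) small-sample factor.
    """
    labels = _labels(g, grouping)
    out = []
    for grp in pd.unique(labels):
        sel = labels == grp
        calls = g.calls[sel]
        nonmiss = ~np.isnan(calls)
        n_called = nonmiss.sum(axis=0)
        informative = n_called > 0
        if not informative.any():
            raise ValueError(f"group {grp!r} has no non-missing calls at any SNP")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(calls, axis=0) / 2.0
            ho = np.nansum(calls == 1, axis=0) / np.where(informative, n_called, 1)
        he = 2.0 * p * (1.0 - p)
        if unbiased:
            nn = 2.0 * n_called
            he = np.where(nn > 1, he * nn / (nn - 1.0), he)
        out.append(
            {
                "group": grp,
                "n": int(sel.sum()),
                "ho": float(np.mean(ho[informative])),
                "he": float(np.mean(he[informative])),
            }
        )
    return pd.DataFrame(out)


def fst_components(
    n_i: np.ndarray, p_i: np.ndarray, h_i: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham per-locus variance components a, b, c.

    Arrays are (r populations, m loci): sample sizes in individuals, allele
    frequencies and observed heterozygote fractions per population.
    """
    n_i = np.asarray(n_i, float)
    r = n_i.shape[0]
    nbar = n_i.mean(axis=0)
    nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
    c = hbar / 2.0
    return a, b, c


def pairwise_fst(g: GenotypeMatrix, grouping="population", exclude=()) -> pd.DataFrame:
    """Pairwise multi-locus Weir-Cockerham theta across groups.

    Loci monomorphic across a pair (zero total component) are skipped.
    Returns a symmetric matrix with zero diagonal, ordered by first
    appearance of the group labels.
    """
    labels = _labels(g, grouping)
    groups = [grp for grp in pd.unique(labels) if grp not in set(exclude)]
    if len(groups) < 2:
        raise ValueError("need at least two groups for Fst")
    per_group = {}
    for grp in groups:
        calls = g.calls[labels == grp]
        if calls.shape[0] < 2:
            raise ValueError(f"group {grp!r} has fewer than two animals")
        nonmiss = ~np.isnan(calls)
        n = nonmiss.sum(axis=0).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(calls, axis=0) / 2.0
            h = np.nansum(calls == 1, axis=0) / np.where(n > 0, n, 1)
        per_group[grp] = (n, p, h)
    mat = pd.DataFrame(0.0, index=groups, columns=groups)
    for ga, gb in itertools.combinations(groups, 2):
        na, pa, ha = per_group[ga]
        nb, pb, hb = per_group[gb]
        usable = (na > 0) & (nb > 0)
        a, b, c = fst_components(
            np.vstack([na, nb])[:, usable],
            np.vstack([pa, pb])[:, usable],
            np.vstack([ha, hb])[:, usable],
        )
        tot = a + b + c
        ok = np.isfinite(tot) & (tot != 0)
        theta = float(a[ok].sum() / tot[ok].sum()) if ok.any() else np.nan
        mat.loc[ga, gb] = mat.loc[gb, ga] = theta
    return mat


class PcaResult:
    """Scores and variance fractions from a genotype PCA."""

    def __init__(self, scores: np.ndarray, var_frac: np.ndarray, animal_ids: np.ndarray,
                 degenerate: bool = False):
        self.scores = scores
        self.var_frac = var_frac
        self.animal_ids = animal_ids
        self.degenerate = degenerate

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores, columns=[f"PC{i+1}" for i in range(self.scores.shape[1])]
        )
        df.insert(0, "animal", self.animal_ids)
        return df


def genotype_pca(
    g: GenotypeMatrix, k: int = 10, scaling: str = "none", exclude_groups=()
) -> PcaResult:
    """PCA of the centred (optionally frequency-scaled) genotype matrix.

    Missing calls are mean-imputed before the decomposition (only here; the
    diversity metrics never impute).  ``scaling='unit'`` divides each SNP
    column by sqrt(2p(1-p)).  Groups named in ``exclude_groups`` (e.g. an
    over-represented year class) are dropped before the decomposition.
    """
    if exclude_groups:
        keep = ~np.isin(np.asarray(g.populations, object), list(exclude_groups))
        g = g.take_animals(keep)
    calls = np.asarray(g.calls, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(calls, axis=0)
    x = np.where(np.isnan(calls), mean[None, :], calls) - mean[None, :]
    if scaling == "unit":
        p = mean / 2.0
        sd = np.sqrt(2.0 * p * (1.0 - p))
        sd[sd == 0] = 1.0
        x = x / sd[None, :]
    elif scaling != "none":
        raise ValueError(f"unknown scaling {scaling!r}")
    rank = min(x.shape)
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank bound {rank}")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = (s**2).sum()
    if total <= 1e-12:
        return PcaResult(
            np.zeros((x.shape[0], k)), np.zeros(k), g.animal_ids, degenerate=True
        )
    scores = u[:, :k] * s[:k]
    return PcaResult(scores, (s[:k] ** 2) / total, g.animal_ids)


def family_correlations(
    div: pd.DataFrame, f_coeffs: pd.Series, survival: pd.Series
) -> pd.DataFrame:
    """Pearson correlations among family mean Ho, inbreeding F and survival.

    ``div`` is the family-level output of :func:`group_heterozygosity`;
    ``f_coeffs`` and ``survival`` are family-indexed.  Zero-variance inputs
    yield an undefined (NaN) r, reported as such.
    """
    merged = div.set_index("group")[["ho"]].join(
        [f_coeffs.rename("f"), survival.rename("survival")], how="inner"
    )
    if len(merged) < 3:
        raise ValueError("need at least three families with complete data")
    rows = []
    for xa, xb in (("ho", "f"), ("ho", "survival"), ("f", "survival")):
        sub = merged[[xa, xb]].dropna()
        if sub[xa].std() == 0 or sub[xb].std() == 0:
            r, p = np.nan, np.nan
        else:
            r, p = sstats.pearsonr(sub[xa], sub[xb])
        rows.append({"pair": f"{xa}~{xb}", "r": r, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)
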