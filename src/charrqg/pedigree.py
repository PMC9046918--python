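"""Pedigree relationships and inbreeding.

Implements the standard numerator-relationship machinery of animal breeding:
topological (parents-before-offspring) sorting, Henderson's tabular method for
the additive relationship matrix A, recursive inbreeding coefficients via
memoised kinships (so F is available without materialising A), and the sparse
direct inverse of A from Henderson's rules accounting for inbreeding.

Unknown parents are handled under two policies:

``zero``
    an unknown parent is an unrelated, non-inbred base animal (classical).
``year_mean``
    an unknown parent is assigned the running mean inbreeding of animals in
    the year class one generation before its offspring (falling back to the
    global running mean), in the spirit of recursive procedures that assume
    nonzero inbreeding for unknown parents.  No bit-compatibility with any
    particular legacy implementation is claimed; the policy is recorded in
    the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = -1

__all__ = [
    "Pedigree",
    "InbreedingResult",
    "PedigreeError",
    "sort_pedigree",
    "a_matrix",
    "a22",
    "inbreeding",
    "a_inverse",
]


class PedigreeError(ValueError):
    """Raised for cyclic parentage or corrupt pedigree input."""


@dataclass
class Pedigree:
    """Animal/sire/dam/year records with unknown parents as ``UNKNOWN``.

    Internally animals are integer indices 0..n-1 into ``ids``; ``sire`` and
    ``dam`` hold parent indices or ``UNKNOWN``.
    """

    ids: np.ndarray            # animal identifiers (str), length n
    sire: np.ndarray           # int indices into ids, UNKNOWN if missing
    dam: np.ndarray
    year: np.ndarray           # int year class per animal

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[a] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - defensive
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from exc

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        """Build from a table with columns animal, sire, dam[, year_class].

        ``"0"``, empty, and NA all denote an unknown parent.  Parents that
        appear only as parents (phantom parents with no own record) get a
        founder record prepended.
        """
        df = df.copy()
        for col in ("animal", "sire", "dam"):
            df[col] = df[col].astype(str).str.strip()
        if "year_class" not in df.columns:
            df["year_class"] = 0
        missing_tokens = {"", "0", "nan", "NA", "None", "."}
        animals = list(df["animal"])
        known = set(animals)
        phantoms = []
        for col in ("sire", "dam"):
            for v in df[col]:
                if v not in missing_tokens and v not in known:
                    known.add(v)
                    phantoms.append(v)
        ids = phantoms + animals
        idx = {a: i for i, a in enumerate(ids)}
        n = len(ids)
        sire = np.full(n, UNKNOWN, dtype=np.int64)
        dam = np.full(n, UNKNOWN, dtype=np.int64)
        year = np.zeros(n, dtype=np.int64)
        yc = pd.to_numeric(df["year_class"], errors="coerce").fillna(0).astype(int)
        for row, y in zip(df.itertuples(index=False), yc):
            i = idx[row.animal]
            year[i] = y
            if row.sire not in missing_tokens:
                sire[i] = idx[row.sire]
            if row.dam not in missing_tokens:
                dam[i] = idx[row.dam]
        if phantoms:
            miny = int(yc.min()) if len(yc) else 0
            for p in phantoms:
                year[idx[p]] = miny - 1
        return cls(np.array(ids, dtype=object), sire, dam, year)

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, dtype=str))

    def to_frame(self) -> pd.DataFrame:
        def name(j):
            return "0" if j == UNKNOWN else self.ids[j]

        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": [name(s) for s in self.sire],
                "dam": [name(d) for d in self.dam],
                "year_class": self.year,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sort_pedigree(ped: Pedigree) -> Pedigree:
    """Topologically sort so parents precede offspring (stable for ties).

    Kahn's algorithm over the parent->offspring DAG; ties are broken by the
    original record order.  A cycle (e.g. an animal that is its own ancestor)
    raises :class:`PedigreeError` naming one member of the cycle.
    """
    n = ped.n
    n_unresolved = np.zeros(n, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for p in (ped.sire[i], ped.dam[i]):
            if p == i:
                raise PedigreeError(f"animal {ped.ids[i]!r} is its own parent")
            if p != UNKNOWN:
                n_unresolved[i] += 1
                children[p].append(i)
    import heapq

    ready = [i for i in range(n) if n_unresolved[i] == 0]
    heapq.heapify(ready)
    order = []
    while ready:
        i = heapq.heappop(ready)
        order.append(i)
        for c in children[i]:
            n_unresolved[c] -= 1
            if n_unresolved[c] == 0:
                heapq.heappush(ready, c)
    if len(order) != n:
        stuck = int(np.flatnonzero(n_unresolved > 0)[0])
        raise PedigreeError(f"cyclic parentage involving animal {ped.ids[stuck]!r}")
    order = np.array(order, dtype=np.int64)
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)

    def remap(p):
        return np.where(p == UNKNOWN, UNKNOWN, rank[np.where(p == UNKNOWN, 0, p)])

    return Pedigree(ped.ids[order], remap(ped.sire)[order], remap(ped.dam)[order], ped.year[order])


def _check_sorted(ped: Pedigree) -> None:
    i = np.arange(ped.n)
    for p in (ped.sire, ped.dam):
        known = p != UNKNOWN
        if np.any(p[known] >= i[known]):
            raise PedigreeError("pedigree is not sorted parents-first; call sort_pedigree")


def a_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    a(i,i) = 1 + 0.5 a(s,d); a(i,j) = 0.5 (a(j,s) + a(j,d)) for j < i, with
    an unknown parent contributing zero.  Requires a sorted pedigree.
    """
    _check_sorted(ped)
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def a22(ped: Pedigree, genotyped_ids) -> np.ndarray:
    """A restricted to the genotyped animals (in the given id order)."""
    idx = ped.index_of(genotyped_ids)
    A = a_matrix(ped)
    return A[np.ix_(idx, idx)]


@dataclass
class InbreedingResult:
    ids: np.ndarray
    f: np.ndarray
    policy: str = "zero"
    unknown_parent_f: dict = field(default_factory=dict)  # animal idx -> assigned F

    def as_series(self) -> pd.Series:
        return pd.Series(self.f, index=self.ids, name="F")

    def family_means(self, families: pd.Series) -> pd.Series:
        """Mean F per family for the animals present in ``families`` (id-indexed)."""
        s = self.as_series().reindex(families.index)
        return s.groupby(families).mean().rename("mean_F")


def inbreeding(ped: Pedigree, unknown_parent_policy: str = "zero") -> InbreedingResult:
    """Per-animal inbreeding F(i) = kinship(sire, dam), without building A.

    Kinships phi(i,j) are computed by the classical recursion with
    memoisation: phi(i,i) = 0.5 (1 + F_i) and, for i sorted after j,
    phi(i,j) = 0.5 (phi(s_i,j) + phi(d_i,j)).

    Under ``year_mean`` an animal with both parents unknown is assigned the
    mean F of previously processed animals in the preceding year class
    (global running mean as fallback); that F enters its self-kinship and so
    propagates to descendants.  The policy never lowers any F below the
    ``zero``-policy value.
    """
    if unknown_parent_policy not in ("zero", "year_mean"):
        raise ValueError(f"unknown policy {unknown_parent_policy!r}")
    _check_sorted(ped)
    n = ped.n
    sire, dam = ped.sire, ped.dam
    f = np.zeros(n)
    self_kin = np.full(n, 0.5)  # phi(i,i)
    memo: dict[tuple[int, int], float] = {}

    def phi(i: int, j: int) -> float:
        # iterative resolution of the kinship recursion (explicit stack)
        if i == UNKNOWN or j == UNKNOWN:
            return 0.0
        stack = [(i, j)]
        while stack:
            a, b = stack[-1]
            if a < b:
                a, b = b, a
            key = (a, b)
            if key in memo:
                stack.pop()
                continue
            if a == b:
                memo[key] = self_kin[a]
                stack.pop()
                continue
            # a is the later animal; recurse through its parents
            deps = []
            for p in (sire[a], dam[a]):
                if p != UNKNOWN:
                    k = (max(p, b), min(p, b))
                    if k not in memo:
                        deps.append((p, b))
            if deps:
                stack.extend(deps)
                continue
            val = 0.0
            for p in (sire[a], dam[a]):
                if p != UNKNOWN:
                    val += 0.5 * memo[(max(p, b), min(p, b))]
            memo[key] = val
            stack.pop()
        a, b = (i, j) if i >= j else (j, i)
        return memo[(a, b)]

    # running means for the year_mean policy
    year_sum: dict[int, float] = {}
    year_cnt: dict[int, int] = {}
    tot_sum, tot_cnt = 0.0, 0
    assigned: dict[int, float] = {}

    for i in range(n):
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            f[i] = phi(s, d)
        elif unknown_parent_policy == "year_mean" and s == UNKNOWN and d == UNKNOWN:
            prev = int(ped.year[i]) - 1
            if year_cnt.get(prev, 0) > 0:
                f[i] = year_sum[prev] / year_cnt[prev]
            elif tot_cnt > 0:
                f[i] = tot_sum / tot_cnt
            else:
                f[i] = 0.0
            assigned[i] = f[i]
        else:
            f[i] = 0.0
        self_kin[i] = 0.5 * (1.0 + f[i])
        memo[(i, i)] = self_kin[i]
        y = int(ped.year[i])
        year_sum[y] = year_sum.get(y, 0.0) + f[i]
        year_cnt[y] = year_cnt.get(y, 0) + 1
        tot_sum += f[i]
        tot_cnt += 1

    return InbreedingResult(ped.ids, f, unknown_parent_policy, assigned)


def a_inverse(ped: Pedigree, fres: InbreedingResult | None = None) -> sp.csr_matrix:
    """Sparse A-inverse from Henderson's rules with inbreeding.

    Mendelian-sampling variance per animal: d = 0.5 - 0.25 (F_s + F_d) when
    both parents are known, 0.75 - 0.25 F_known for one known parent, and 1
    for none.  Contributions 1/d at the (animal, sire, dam) pattern.
    """
    _check_sorted(ped)
    if fres is None:
        fres = inbreeding(ped)
    f = fres.f
    n = ped.n
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        parents = [p for p in (s, d) if p != UNKNOWN]
        if len(parents) == 2:
            di = 0.5 - 0.25 * (f[s] + f[d])
        elif len(parents) == 1:
            di = 0.75 - 0.25 * f[parents[0]]
        else:
            di = 1.0
        if di <= 0:
            raise PedigreeError(f"non-positive Mendelian sampling variance for {ped.ids[i]!r}")
        alpha = 1.0 / di
        rows.append(i); cols.append(i); vals.append(alpha)
        for p in parents:
            rows += [i, p]; cols += [p, i]; vals += [-0.5 * alpha, -0.5 * alpha]
        for p in parents:
            for q in parents:
                rows.append(p); cols.append(q); vals.append(0.25 * alpha)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
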