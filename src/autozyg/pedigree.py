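"""Pedigree parsing and Wright's inbreeding coefficient F_PED.

F is the probability that the two alleles an individual carries at a
random autosomal locus are identical by descent, with pedigree founders
assumed unrelated and non-inbred.  The default computation is the
Meuwissen & Luo recursion over the diagonal of the numerator
relationship matrix A (F_i = A_ii - 1), which needs memory linear in the
pedigree; a memoised kinship recursion is kept as an internal
cross-check.
"""

from __future__ import annotations

import heapq
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNKNOWN = "0"


@dataclass
class Pedigree:
    """Acyclic id -> (sire, dam) table in topological order.

    ``sire`` / ``dam`` hold positional indices into ``ids`` (-1 for an
    unknown parent).  Parents always precede offspring.  Parents that
    appear only in a parent column are materialised as founder records.
    """

    ids: list[str]
    sire: np.ndarray = field(repr=False)
    dam: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if self.sire.shape != (n,) or self.dam.shape != (n,):
            raise ValueError("sire/dam arrays must match id count")
        for arr in (self.sire, self.dam):
            if ((arr < -1) | (arr >= n)).any():
                raise ValueError("parent index out of range")
            bad = np.flatnonzero((arr >= np.arange(n)) & (arr != -1))
            if bad.size:
                raise ValueError(
                    f"parent does not precede offspring at {self.ids[bad[0]]!r}"
                )

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]]
    ) -> "Pedigree":
        """Build from (id, sire, dam) strings; '0'/''/'NA' mean unknown.

        Records may arrive in any order; a topological sort is applied.
        Cycles (an individual among its own ancestors) are an error.
        """
        recs = [
            (str(i), str(s), str(d)) for i, s, d in records
        ]
        def known(x: str) -> bool:
            return x not in (UNKNOWN, "", "NA", "na", ".")

        parent_of: dict[str, tuple[str | None, str | None]] = {}
        order_seen: list[str] = []
        for iid, s, d in recs:
            if iid in parent_of:
                raise ValueError(f"duplicate pedigree record for {iid!r}")
            if known(s) and s == iid or known(d) and d == iid:
                raise ValueError(f"individual {iid!r} listed as its own parent")
            parent_of[iid] = (s if known(s) else None, d if known(d) else None)
            order_seen.append(iid)
        # parents without a record become implicit founders
        for iid in order_seen:
            for par in parent_of[iid]:
                if par is not None and par not in parent_of:
                    parent_of[par] = (None, None)

        # Kahn topological sort, stable in first-seen order
        all_ids = list(parent_of)
        children: dict[str, list[str]] = {i: [] for i in all_ids}
        indeg = {i: 0 for i in all_ids}
        for iid in all_ids:
            for par in parent_of[iid]:
                if par is not None:
                    children[par].append(iid)
                    indeg[iid] += 1
        queue = [i for i in all_ids if indeg[i] == 0]
        topo: list[str] = []
        while queue:
            iid = queue.pop(0)
            topo.append(iid)
            for ch in children[iid]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if len(topo) != len(all_ids):
            cycle = sorted(set(all_ids) - set(topo))
            raise ValueError(
                f"pedigree contains a cycle involving: {', '.join(cycle)}"
            )
        index = {iid: k for k, iid in enumerate(topo)}
        sire = np.array(
            [index[parent_of[i][0]] if parent_of[i][0] else -1 for i in topo],
            dtype=np.int64,
        )
        dam = np.array(
            [index[parent_of[i][1]] if parent_of[i][1] else -1 for i in topo],
            dtype=np.int64,
        )
        return cls(topo, sire, dam)

    # -- accessors ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    def founders(self) -> list[str]:
        return [
            iid
            for iid, s, d in zip(self.ids, self.sire, self.dam)
            if s == -1 and d == -1
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [self.ids[s] if s >= 0 else UNKNOWN for s in self.sire],
                "dam": [self.ids[d] if d >= 0 else UNKNOWN for d in self.dam],
            }
        )

    def write(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, header=False)


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    """Read a 3+ column whitespace/TSV pedigree file (id, sire, dam)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{os.fspath(path)}:{lineno}: expected at least 3 columns"
                )
            records.append(tuple(fields[:3]))
    if records and records[0] == ("id", "sire", "dam"):
        records = records[1:]
    if not records:
        raise ValueError(f"{os.fspath(path)}: empty pedigree")
    return Pedigree.from_records(records)


def f_ped(pedigree: Pedigree) -> pd.Series:
    """Inbreeding coefficient for every individual (Meuwissen & Luo).

    For each individual the diagonal element of A is accumulated as
    A_ii = sum_j L_ij^2 d_j over the individual's ancestors j, where
    d_j is the within-family segregation variance and L_ij the path
    coefficient; F_i = A_ii - 1.  Individuals with an unknown parent
    have F = 0 (an unknown parent acts as a unique phantom founder).
    """
    n = pedigree.n
    sire, dam = pedigree.sire, pedigree.dam
    F = np.zeros(n)
    d = np.zeros(n)
    for i in range(n):
        s, t = sire[i], dam[i]
        d[i] = (
            1.0
            - (0.25 * (1.0 + F[s]) if s >= 0 else 0.0)
            - (0.25 * (1.0 + F[t]) if t >= 0 else 0.0)
        )
        if s < 0 or t < 0:
            F[i] = 0.0
            continue
        # accumulate A_ii over ancestors, youngest first
        coef: dict[int, float] = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            c = coef.pop(j, 0.0)
            if c == 0.0:
                continue
            a_ii += c * c * d[j]
            for par in (sire[j], dam[j]):
                if par >= 0:
                    if par not in coef:
                        heapq.heappush(heap, -int(par))
                    coef[par] = coef.get(par, 0.0) + 0.5 * c
        F[i] = a_ii - 1.0
    return pd.Series(F, index=pd.Index(pedigree.ids, name="id"), name="f_ped")


def _f_ped_by_kinship(pedigree: Pedigree) -> pd.Series:
    """Cross-check: F_i = kinship(sire_i, dam_i) by memoised recursion."""
    sire, dam = pedigree.sire, pedigree.dam
    cache: dict[tuple[int, int], float] = {}

    def phi(a: int, b: int) -> float:
        if a < 0 or b < 0:
            return 0.0
        if a < b:
            a, b = b, a
        key = (a, b)
        if key in cache:
            return cache[key]
        if a == b:
            val = 0.5 * (1.0 + phi(sire[a], dam[a]))
        else:
            # a is the younger (later topological index): recurse on its parents
            val = 0.5 * (phi(sire[a], b) + phi(dam[a], b))
        cache[key] = val
        return val

    values = [phi(int(sire[i]), int(dam[i])) for i in range(pedigree.n)]
    return pd.Series(
        values, index=pd.Index(pedigree.ids, name="id"), name="f_ped"
    )


def gene_drop_f(
    pedigree: Pedigree, n_drops: int = 10_000, seed: int | None = None
) -> pd.Series:
    """Monte-Carlo F: drop founder alleles through the pedigree at a
    single unlinked locus and count autozygous outcomes per individual."""
    rng = np.random.default_rng(seed)
    n = pedigree.n
    sire, dam = pedigree.sire, pedigree.dam
    hap_a = np.empty((n, n_drops), dtype=np.int64)
    hap_b = np.empty((n, n_drops), dtype=np.int64)
    fresh = 0  # unknown parents contribute unique (phantom founder) labels
    for i in range(n):
        for par, tgt in ((sire[i], hap_a), (dam[i], hap_b)):
            if par < 0:
                tgt[i] = np.arange(fresh, fresh + n_drops)
                fresh += n_drops
            else:
                pick = rng.integers(0, 2, size=n_drops).astype(bool)
                tgt[i] = np.where(pick, hap_b[par], hap_a[par])
    auto = (hap_a == hap_b).mean(axis=1)
    return pd.Series(
        auto, index=pd.Index(pedigree.ids, name="id"), name="f_mc"
    )
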