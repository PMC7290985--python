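"""Independent oracles used by the test suite.

Everything here is deliberately written with plain-Python loops and
exact rational arithmetic, independent of the vectorised implementation
paths it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np

from autozyg.genotypes import MISSING


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test by full enumeration with exact rationals
# ---------------------------------------------------------------------------

def hwe_exact_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact HWE p-value from the conditional multinomial
    distribution of heterozygote counts, in exact rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0

    def weight(h: int) -> Fraction:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return Fraction(
            factorial(n), factorial(hom_rare) * factorial(h) * factorial(hom_common)
        ) * 2**h

    weights = {h: weight(h) for h in range(rare % 2, rare + 1, 2)}
    total = sum(weights.values())
    w_obs = weights[n_Aa]
    return float(sum(w for w in weights.values() if w <= w_obs) / total)


# ---------------------------------------------------------------------------
# quadratic sliding-window scan and brute-force run enumeration
# ---------------------------------------------------------------------------

def window_proportions_oracle(calls, params) -> list[float]:
    """Per-SNP homozygous-window proportion by direct window enumeration."""
    calls = list(calls)
    n = len(calls)
    w = min(params.window_size_snp, n)
    hom_win = []
    for s in range(n - w + 1):
        window = calls[s : s + w]
        het = sum(1 for c in window if c == 1)
        mis = sum(1 for c in window if c == MISSING)
        hom_win.append(
            het <= params.max_het_in_window
            and mis <= params.max_missing_in_window
        )
    props = []
    for i in range(n):
        starts = range(max(0, i - w + 1), min(i, n - w) + 1)
        covered = [hom_win[s] for s in starts]
        props.append(sum(covered) / len(covered))
    return props


def roh_intervals_oracle(calls, positions, params) -> list[tuple[int, int, int]]:
    """Brute-force ROH enumeration on one chromosome of one individual.

    Tests every contiguous SNP interval for eligibility (every SNP in an
    eligible window proportion, no internal gap above the maximum),
    keeps the maximal such intervals, then applies the run constraints
    (minimum SNPs, minimum length, density).  Returns
    (start_bp, end_bp, n_snp) triples.
    """
    n = len(calls)
    props = window_proportions_oracle(calls, params)
    eligible = [p >= 1.0 - params.window_threshold for p in props]

    def gap_ok(i: int) -> bool:  # gap between SNP i and i+1
        return positions[i + 1] - positions[i] <= params.max_gap_bp

    candidates = []
    for s in range(n):
        if not eligible[s]:
            continue
        e = s
        while e + 1 < n and eligible[e + 1] and gap_ok(e):
            e += 1
        left_maximal = s == 0 or not eligible[s - 1] or not gap_ok(s - 1)
        if left_maximal:
            candidates.append((s, e))

    out = []
    for s, e in candidates:
        n_snp = e - s + 1
        length = positions[e] - positions[s]
        if n_snp < params.min_snp:
            continue
        if length < params.min_length_bp:
            continue
        if length / n_snp > params.min_density_bp_per_snp:
            continue
        out.append((int(positions[s]), int(positions[e]), n_snp))
    return out


# ---------------------------------------------------------------------------
# Wright path-counting inbreeding oracle
# ---------------------------------------------------------------------------

def wright_path_counting_f(pedigree) -> dict[str, float]:
    """F by enumerating common-ancestor paths (Wright's formula).

    F_i = sum over common ancestors A and over pairs of ancestor paths
    (sire -> A, dam -> A) sharing no individual except A of
    (1/2)^(n_s + n_d + 1) (1 + F_A).
    """
    sire, dam, ids = pedigree.sire, pedigree.dam, pedigree.ids
    path_cache: dict[int, list[tuple[int, frozenset, int]]] = {}

    def ancestor_paths(x: int) -> list[tuple[int, frozenset, int]]:
        """All (ancestor, nodes-on-path, n_edges) chains from x upward."""
        if x < 0:
            return []
        if x in path_cache:
            return path_cache[x]
        paths = [(x, frozenset([x]), 0)]
        for par in (sire[x], dam[x]):
            if par >= 0:
                for anc, nodes, length in ancestor_paths(int(par)):
                    paths.append((anc, nodes | {x}, length + 1))
        path_cache[x] = paths
        return paths

    f_cache: dict[int, float] = {}

    def f_of(i: int) -> float:
        if i in f_cache:
            return f_cache[i]
        s, d = int(sire[i]), int(dam[i])
        if s < 0 or d < 0:
            f_cache[i] = 0.0
            return 0.0
        total = 0.0
        dam_paths = ancestor_paths(d)
        for anc_s, nodes_s, len_s in ancestor_paths(s):
            for anc_d, nodes_d, len_d in dam_paths:
                if anc_s != anc_d:
                    continue
                if nodes_s & nodes_d != frozenset([anc_s]):
                    continue
                total += 0.5 ** (len_s + len_d + 1) * (1.0 + f_of(anc_s))
        f_cache[i] = total
        return total

    return {ids[i]: f_of(i) for i in range(pedigree.n)}


def random_pedigree(n: int, rng: np.random.Generator, p_founder: float = 0.3):
    """Random acyclic pedigree of *n* members (parents drawn from earlier
    individuals, occasionally unknown)."""
    from autozyg.pedigree import Pedigree

    records = []
    for i in range(n):
        iid = f"ind{i}"
        if i < 2 or rng.random() < p_founder:
            records.append((iid, "0", "0"))
        else:
            s = f"ind{rng.integers(i)}"
            d = f"ind{rng.integers(i)}"
            records.append((iid, s, d))
    return Pedigree.from_records(records)


# ---------------------------------------------------------------------------
# misc genotype fixtures
# ---------------------------------------------------------------------------

def toy_marker_map(n: int, spacing_bp: int = 30_000, chrom: str = "chr1"):
    from autozyg.genotypes import MarkerMap

    return MarkerMap.from_arrays(
        [f"{chrom}_m{i}" for i in range(n)],
        [chrom] * n,
        [1 + i * spacing_bp for i in range(n)],
        ["A"] * n,
        ["C"] * n,
    )


def random_roh_chromosome(n_snp: int, rng: np.random.Generator):
    """A single-individual chromosome with homozygous stretches, noise
    hets/missing and occasionally oversized gaps — exercises every ROH
    constraint."""
    calls = np.zeros(n_snp, dtype=np.int8)
    # background heterozygosity
    het_rate = rng.uniform(0.05, 0.4)
    calls[rng.random(n_snp) < het_rate] = 1
    # implant 1-3 homozygous stretches
    for _ in range(int(rng.integers(1, 4))):
        start = int(rng.integers(0, max(1, n_snp - 60)))
        length = int(rng.integers(40, 150))
        calls[start : start + length] = np.where(
            rng.random(min(length, n_snp - start)) < 0.5, 0, 2
        )
    # sprinkle isolated hets and missing
    idx = rng.choice(n_snp, size=max(1, n_snp // 40), replace=False)
    calls[idx] = np.where(rng.random(idx.size) < 0.5, 1, MISSING)
    # positions: mostly ~25 kb spacing, occasional >500 kb gap
    gaps = rng.integers(5_000, 45_000, size=n_snp)
    wide = rng.random(n_snp) < 0.01
    gaps[wide] = rng.integers(500_001, 900_000, size=int(wide.sum()))
    positions = np.cumsum(gaps)
    return calls, positions
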