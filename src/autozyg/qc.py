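"""Marker/sample quality control and cross-population marker intersection.

Filters are applied in a fixed, documented order so that the per-filter
removal counts in :class:`QCReport` are reproducible:

1. sample call rate (individuals with < ``call_rate_min`` non-missing dropped)
2. marker call rate (recomputed on retained samples)
3. minor allele frequency (non-missing calls only)
4. Hardy-Weinberg exact test

A marker is counted once, against the first filter that removes it.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, MarkerMap


@dataclass
class QCReport:
    """Bookkeeping for one population's QC pass.

    Marker removals partition the input panel:
    ``n_input_markers = n_retained + n_removed_callrate_marker +
    n_removed_maf + n_removed_hwe + n_removed_not_common``.
    ``n_removed_sample`` counts individuals, not markers.
    """

    population_label: str = ""
    n_input_markers: int = 0
    n_input_samples: int = 0
    n_removed_sample: int = 0
    n_removed_callrate_marker: int = 0
    n_removed_maf: int = 0
    n_removed_hwe: int = 0
    n_removed_not_common: int = 0
    n_retained: int = 0
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    call_rate_min: float = 0.90

    def check(self) -> None:
        total = (
            self.n_retained
            + self.n_removed_callrate_marker
            + self.n_removed_maf
            + self.n_removed_hwe
            + self.n_removed_not_common
        )
        if total != self.n_input_markers:
            raise AssertionError(
                f"QC counts do not partition input markers: {total} != "
                f"{self.n_input_markers}"
            )

    def apply_intersection(self, n_common: int) -> None:
        """Record markers dropped by the common-marker intersection."""
        if n_common > self.n_retained:
            raise ValueError("intersection cannot grow the marker set")
        self.n_removed_not_common += self.n_retained - n_common
        self.n_retained = n_common

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def to_text(self) -> str:
        d = asdict(self)
        width = max(len(k) for k in d)
        return "\n".join(f"{k.ljust(width)}  {v}" for k, v in d.items())


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int, midp: bool = False) -> float:
    """Two-sided exact Hardy-Weinberg test for one biallelic marker.

    Conditional on the observed allele counts, enumerates every possible
    heterozygote count and sums the probabilities of all configurations
    no more probable than the observed one (the standard exact HWE test;
    ``midp`` halves the observed configuration's own contribution).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped individuals at marker")
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0

    # P(h het | allele counts), computed by the stable two-way recurrence
    # from the mode of the distribution.
    n_h = rare // 2 * 2 + rare % 2  # max het count with correct parity
    probs = np.zeros(n_h // 2 + 1)
    # het counts h = rare % 2, rare % 2 + 2, ..., n_h  (index k -> h = 2k + parity)
    parity = rare % 2
    mode = int(round(rare * (2 * n - rare) / (2.0 * n - 1.0)))
    if mode % 2 != parity:
        mode += 1 if mode < n_h else -1
    k_mode = (mode - parity) // 2
    probs[k_mode] = 1.0
    # going down: P(h-2)/P(h) = h(h-1) / ((rare-h+2)(2n-rare-h+2))
    for h in range(mode, 1, -2):
        k = (h - parity) // 2
        probs[k - 1] = probs[k] * h * (h - 1) / (
            (rare - h + 2.0) * (2 * n - rare - h + 2.0)
        )
    # going up: P(h+2)/P(h) = (rare-h)(2n-rare-h) / ((h+2)(h+1))
    for h in range(mode, n_h - 1, 2):
        k = (h - parity) // 2
        probs[k + 1] = probs[k] * (rare - h) * (2 * n - rare - h) / (
            (h + 2.0) * (h + 1.0)
        )
    probs /= probs.sum()

    obs_het = n_Aa
    if obs_het % 2 != parity or obs_het > n_h:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = probs[(obs_het - parity) // 2]
    tail = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    if midp:
        tail -= 0.5 * p_obs
    return float(min(tail, 1.0))


def qc_filter(
    g: GenotypeMatrix,
    marker_map: MarkerMap,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    call_rate_min: float = 0.90,
) -> tuple[GenotypeMatrix, MarkerMap, QCReport]:
    """Apply sample and marker QC; returns filtered data plus a report."""
    if g.n_markers != marker_map.n_markers:
        raise ValueError("genotype matrix and marker map disagree on marker count")
    report = QCReport(
        population_label=g.population_label,
        n_input_markers=g.n_markers,
        n_input_samples=g.n_individuals,
        maf_min=maf_min,
        hwe_p_min=hwe_p_min,
        call_rate_min=call_rate_min,
    )

    # 1. sample call rate
    keep_ind = np.flatnonzero(g.call_rate("individual") >= call_rate_min)
    report.n_removed_sample = g.n_individuals - keep_ind.size
    if keep_ind.size == 0:
        raise ValueError("all samples removed by call-rate filter")
    g = g.subset_individuals(keep_ind)

    # 2. marker call rate
    alive = g.call_rate("marker") >= call_rate_min
    report.n_removed_callrate_marker = int((~alive).sum())

    # 3. MAF (non-missing calls only)
    maf = g.minor_allele_frequencies()
    fail_maf = alive & ((maf < maf_min) | np.isnan(maf))
    report.n_removed_maf = int(fail_maf.sum())
    alive &= ~fail_maf

    # 4. HWE exact test
    counts = g.genotype_counts()
    fail_hwe = np.zeros_like(alive)
    for j in np.flatnonzero(alive):
        p = hwe_exact_test(*counts[j])
        if p < hwe_p_min:
            fail_hwe[j] = True
    report.n_removed_hwe = int(fail_hwe.sum())
    alive &= ~fail_hwe

    report.n_retained = int(alive.sum())
    report.check()
    if report.n_retained == 0:
        raise ValueError("all markers removed by QC")
    keep = np.flatnonzero(alive)
    return g.subset_markers(keep), marker_map.subset(keep), report


def intersect_markers(
    populations: list[tuple[GenotypeMatrix, MarkerMap]],
) -> list[tuple[GenotypeMatrix, MarkerMap]]:
    """Restrict every population to the markers shared by all of them.

    Marker order follows the first population's map; all outputs share an
    identical map.  Chromosome/position disagreements for a shared marker
    id are an error.
    """
    if len(populations) < 2:
        raise ValueError("need at least two populations to intersect")
    shared = set(populations[0][1].marker_ids)
    for _, mmap in populations[1:]:
        shared &= set(mmap.marker_ids)
    if not shared:
        raise ValueError("no markers shared across populations")
    ref_ids = [m for m in populations[0][1].marker_ids if m in shared]

    out: list[tuple[GenotypeMatrix, MarkerMap]] = []
    ref_coords = None
    for g, mmap in populations:
        idx = mmap.indexer(ref_ids)
        g2, m2 = g.subset_markers(idx), mmap.subset(idx)
        coords = list(zip(m2.table["chromosome"], m2.table["position_bp"]))
        if ref_coords is None:
            ref_coords = coords
        elif coords != ref_coords:
            raise ValueError(
                "shared markers have conflicting coordinates across populations"
            )
        out.append((g2, m2))
    return out
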