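"""Gene-dropping simulator with ground-truth identity-by-descent.

Founder chromosomes carry unique allele labels; each meiosis recombines
the two parental haplotype mosaics with crossovers drawn as a Poisson
process (Haldane model, no interference) at a configurable cM/Mb rate.
Offspring haplotypes are therefore mosaics of founder labels, genotypes
are read off marker positions, and true autozygosity is the fraction of
the genome where the two haplotype labels coincide — an exact oracle for
every downstream estimator.

:func:`make_study_design` emulates a two-line breeding-nucleus design:
one ancestral pool split into two closed, drift-only lines bred for a
fixed number of discrete generations, optionally crossed in the final
generation to produce an admixed F1 cohort (low autozygosity, no long
runs of homozygosity expected).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MarkerMap
from .pedigree import Pedigree

#: Full-panel genome length emulated by the full-scale preset (bp).
FULL_GENOME_BP = 1_685_790_000


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome lengths, marker density and recombination rate."""

    chromosome_lengths_bp: tuple[int, ...] = (50_000_000,) * 5
    markers_per_mb: float = 100.0
    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if not self.chromosome_lengths_bp:
            raise ValueError("need at least one chromosome")
        if any(l <= 0 for l in self.chromosome_lengths_bp):
            raise ValueError("chromosome lengths must be positive")
        if self.markers_per_mb <= 0:
            raise ValueError("markers_per_mb must be positive")
        if self.cm_per_mb < 0:
            raise ValueError("cm_per_mb must be non-negative")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_lengths_bp)

    @property
    def chromosome_names(self) -> list[str]:
        width = len(str(self.n_chromosomes))
        return [f"chr{i + 1:0{width}d}" for i in range(self.n_chromosomes)]

    @property
    def total_length_bp(self) -> int:
        return int(sum(self.chromosome_lengths_bp))

    @classmethod
    def desk_scale(cls, markers_per_mb: float = 100.0) -> "GenomeSpec":
        """Small genome for fast tests: 5 chromosomes x 50 Mb."""
        return cls((50_000_000,) * 5, markers_per_mb, 1.0)

    @classmethod
    def full_scale(cls, markers_per_mb: float = 60.0) -> "GenomeSpec":
        """30 chromosomes with descending lengths summing to 1685.79 Mb."""
        raw = np.linspace(90e6, 25e6, 30)
        lengths = np.floor(raw * FULL_GENOME_BP / raw.sum()).astype(np.int64)
        lengths[-1] += FULL_GENOME_BP - lengths.sum()
        return cls(tuple(int(l) for l in lengths), markers_per_mb, 1.0)


# A haplotype mosaic on one chromosome: (ends, labels) where ends are
# ascending segment end positions (bp, last = chromosome length) and
# labels are founder-haplotype integers covering (prev_end, end].
Mosaic = tuple[np.ndarray, np.ndarray]


@dataclass
class FounderSet:
    """Founder haplotype alleles plus the marker map they live on."""

    marker_map: MarkerMap
    haplotype_alleles: np.ndarray = field(repr=False)  # (2n, m) of 0/1
    spec: GenomeSpec = field(default_factory=GenomeSpec)
    allele_frequencies: np.ndarray = field(default=None, repr=False)

    @property
    def n_founders(self) -> int:
        return self.haplotype_alleles.shape[0] // 2


@dataclass
class SimTruth:
    """Per-individual founder-label mosaics and derived autozygosity."""

    spec: GenomeSpec
    mosaics: dict[str, list[tuple[Mosaic, Mosaic]]] = field(repr=False)

    def true_autozygosity(self, individual_id: str) -> float:
        """Fraction of the genome where both haplotypes share a label."""
        total = self.spec.total_length_bp
        ibd = 0
        for (ends_a, lab_a), (ends_b, lab_b) in self.mosaics[individual_id]:
            cuts = np.union1d(ends_a, ends_b)
            ia = np.searchsorted(ends_a, cuts)
            ib = np.searchsorted(ends_b, cuts)
            widths = np.diff(np.concatenate([[0], cuts]))
            ibd += int(widths[lab_a[ia] == lab_b[ib]].sum())
        return ibd / total

    def true_autozygosity_series(self) -> pd.Series:
        return pd.Series(
            {iid: self.true_autozygosity(iid) for iid in self.mosaics},
            name="true_f",
        )

    def autozygous_segments(
        self, individual_id: str
    ) -> list[tuple[str, int, int]]:
        """Maximal (chromosome, start, end] tracts of shared labels."""
        out = []
        names = self.spec.chromosome_names
        for c, ((ends_a, lab_a), (ends_b, lab_b)) in enumerate(
            self.mosaics[individual_id]
        ):
            cuts = np.union1d(ends_a, ends_b)
            ia = np.searchsorted(ends_a, cuts)
            ib = np.searchsorted(ends_b, cuts)
            same = lab_a[ia] == lab_b[ib]
            start = 0
            for k, end in enumerate(cuts):
                if same[k]:
                    if out and out[-1][0] == names[c] and out[-1][2] == start:
                        out[-1] = (names[c], out[-1][1], int(end))
                    else:
                        out.append((names[c], int(start), int(end)))
                start = int(end)
        return out

    def write_jsonl(self, path: str | os.PathLike) -> None:
        """One JSON record per individual: labelled segments per haplotype."""
        names = self.spec.chromosome_names
        with open(path, "w") as fh:
            for iid, chroms in self.mosaics.items():
                rec = {
                    "id": iid,
                    "chromosomes": [
                        {
                            "name": names[c],
                            "hap_a": {
                                "ends": ends_a.tolist(),
                                "labels": lab_a.tolist(),
                            },
                            "hap_b": {
                                "ends": ends_b.tolist(),
                                "labels": lab_b.tolist(),
                            },
                        }
                        for c, ((ends_a, lab_a), (ends_b, lab_b)) in enumerate(
                            chroms
                        )
                    ],
                }
                fh.write(json.dumps(rec) + "\n")


def simulate_founders(
    n: int,
    spec: GenomeSpec | None = None,
    maf_dist: tuple[str, float, float] = ("uniform", 0.05, 0.5),
    seed: int | np.random.Generator | None = None,
) -> FounderSet:
    """Draw founder haplotypes and a marker map.

    Marker positions are uniform within each chromosome at the spec's
    density; per-marker alternate-allele frequencies come from
    ``maf_dist`` (default Uniform(0.05, 0.5)) and founder haplotype
    alleles are Bernoulli draws at that frequency.  Each of the 2n
    founder haplotypes carries a unique label genome-wide.
    """
    if n < 2:
        raise ValueError("need at least two founders")
    spec = spec or GenomeSpec()
    kind, lo, hi = maf_dist
    if kind != "uniform":
        raise ValueError(f"unsupported maf distribution {kind!r}")
    if not (0.0 <= lo <= hi <= 0.5):
        raise ValueError("maf bounds must satisfy 0 <= low <= high <= 0.5")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    marker_ids, chroms, positions = [], [], []
    for name, length in zip(spec.chromosome_names, spec.chromosome_lengths_bp):
        m = max(2, int(round(length / 1e6 * spec.markers_per_mb)))
        pos = np.unique(rng.integers(1, length + 1, size=m))
        while pos.size < m:  # top up after collisions
            extra = rng.integers(1, length + 1, size=m - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(pos)
        positions.append(pos)
        chroms += [name] * len(pos)
        marker_ids += [f"{name}_snp{k + 1}" for k in range(len(pos))]
    positions = np.concatenate(positions)
    mmap = MarkerMap.from_arrays(marker_ids, chroms, positions)

    m_total = mmap.n_markers
    freqs = rng.uniform(lo, hi, size=m_total)
    alleles = (rng.random((2 * n, m_total)) < freqs).astype(np.int8)
    return FounderSet(mmap, alleles, spec, freqs)


def _slice_mosaic(mosaic: Mosaic, lo: int, hi: int) -> tuple[list[int], list[int]]:
    """Segments of a mosaic restricted to the interval (lo, hi]."""
    ends, labels = mosaic
    first = np.searchsorted(ends, lo, side="right")
    out_ends, out_labels = [], []
    for k in range(first, len(ends)):
        out_ends.append(min(int(ends[k]), hi))
        out_labels.append(int(labels[k]))
        if ends[k] >= hi:
            break
    return out_ends, out_labels


def meiosis(
    hap_a: Mosaic,
    hap_b: Mosaic,
    chrom_length_bp: int,
    cm_per_mb: float,
    rng: np.random.Generator,
) -> Mosaic:
    """One gamete: recombine two parental mosaics (Haldane crossovers)."""
    mean_crossovers = chrom_length_bp / 1e6 * cm_per_mb / 100.0
    k = rng.poisson(mean_crossovers) if mean_crossovers > 0 else 0
    cuts = (
        np.sort(rng.integers(1, chrom_length_bp, size=k)) if k else
        np.empty(0, dtype=np.int64)
    )
    phase = int(rng.integers(0, 2))
    sources = (hap_a, hap_b)
    bounds = np.concatenate([[0], cuts, [chrom_length_bp]])
    ends: list[int] = []
    labels: list[int] = []
    for piece, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        if hi <= lo:
            continue
        seg_ends, seg_labels = _slice_mosaic(
            sources[(phase + piece) % 2], int(lo), int(hi)
        )
        for e, l in zip(seg_ends, seg_labels):
            if labels and labels[-1] == l:
                ends[-1] = e  # merge adjacent same-label segments
            else:
                ends.append(e)
                labels.append(l)
    return np.asarray(ends, dtype=np.int64), np.asarray(labels, dtype=np.int64)


def gene_drop(
    pedigree: Pedigree,
    founders: FounderSet,
    seed: int | np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Transmit labelled founder chromosomes through a pedigree.

    Pedigree founders are assigned to simulated founders in topological
    order; individuals with an unknown parent draw a fresh founder for
    the missing side.  Returns genotypes at the founder marker map plus
    the full label mosaic truth.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    spec = founders.spec
    mmap = founders.marker_map
    ped_founders = pedigree.founders()
    half_founders = sum(
        1
        for s, d in zip(pedigree.sire, pedigree.dam)
        if (s < 0) != (d < 0)
    )
    needed = len(ped_founders) + half_founders
    if needed > founders.n_founders:
        raise ValueError(
            f"pedigree needs {needed} founders (incl. phantom parents) but "
            f"only {founders.n_founders} were simulated"
        )

    lengths = spec.chromosome_lengths_bp
    blocks = mmap.chrom_blocks()
    positions = mmap.positions

    next_founder = 0

    def founder_mosaics(idx: int) -> list[tuple[Mosaic, Mosaic]]:
        return [
            (
                (np.array([L], dtype=np.int64), np.array([2 * idx], dtype=np.int64)),
                (np.array([L], dtype=np.int64), np.array([2 * idx + 1], dtype=np.int64)),
            )
            for L in lengths
        ]

    mosaics: dict[str, list[tuple[Mosaic, Mosaic]]] = {}
    for i, iid in enumerate(pedigree.ids):
        s, d = int(pedigree.sire[i]), int(pedigree.dam[i])
        if s < 0 and d < 0:
            mosaics[iid] = founder_mosaics(next_founder)
            next_founder += 1
            continue
        per_chrom: list[tuple[Mosaic, Mosaic]] = []
        phantom: list[tuple[Mosaic, Mosaic]] | None = None
        if s < 0 or d < 0:
            phantom = founder_mosaics(next_founder)
            next_founder += 1
        for c, L in enumerate(lengths):
            gametes = []
            for par in (s, d):
                if par >= 0:
                    pa, pb = mosaics[pedigree.ids[par]][c]
                else:
                    pa, pb = phantom[c]
                gametes.append(meiosis(pa, pb, L, spec.cm_per_mb, rng))
            per_chrom.append((gametes[0], gametes[1]))
        mosaics[iid] = per_chrom

    # read genotypes off marker positions
    n = pedigree.n
    calls = np.empty((n, mmap.n_markers), dtype=np.int8)
    hap_alleles = founders.haplotype_alleles
    for i, iid in enumerate(pedigree.ids):
        for c, chrom in enumerate(spec.chromosome_names):
            sl = blocks.get(chrom)
            if sl is None:
                continue
            pos = positions[sl]
            marker_idx = np.arange(sl.start, sl.stop)
            dosage = np.zeros(len(pos), dtype=np.int8)
            for ends, labels in mosaics[iid][c]:
                seg = np.searchsorted(ends, pos, side="left")
                dosage += hap_alleles[labels[seg], marker_idx]
            calls[i, sl] = dosage
    genotypes = GenotypeMatrix(list(pedigree.ids), calls, "sim")
    return genotypes, SimTruth(spec, mosaics)


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """Simulated two-line breeding design with optional F1 cross."""

    populations: dict[str, GenotypeMatrix]
    marker_map: MarkerMap
    pedigree: Pedigree
    truth: SimTruth
    founders: FounderSet
    all_genotypes: GenotypeMatrix = field(repr=False)

    def write(self, outdir: str | os.PathLike, dialect: str = "ped") -> None:
        """PLINK files per population + pedigree TSV + truth JSONL."""
        from .plink import write_plink

        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        for name, g in self.populations.items():
            write_plink(g, self.marker_map, os.path.join(outdir, name), dialect)
        self.pedigree.write(os.path.join(outdir, "pedigree.tsv"))
        self.truth.write_jsonl(os.path.join(outdir, "truth.jsonl"))


def make_study_design(
    g_line: int = 8,
    n_per_gen: int = 30,
    cross: bool = True,
    seed: int | np.random.Generator | None = None,
    spec: GenomeSpec | None = None,
    n_cross: int | None = None,
    maf_dist: tuple[str, float, float] = ("uniform", 0.05, 0.5),
) -> StudyDesign:
    """Simulate two closed lines plus an optional F1 cross cohort.

    An ancestral pool of ``2 * n_per_gen`` unrelated founders is split
    disjointly into lines A and B.  Each line breeds ``g_line`` discrete
    generations of ``n_per_gen`` offspring; parents are drawn at random
    (sires from even, dams from odd positions of the previous
    generation) with no full-sib avoidance, so drift alone accumulates
    inbreeding.  With ``cross``, an F1 cohort mates line-A sires of
    generation ``g_line - 1`` to line-B dams of generation ``g_line``,
    mirroring a cross made to limit inbreeding.  Genotyped cohorts are
    the final generation of each line (POP_A, POP_B) and the F1 (POP_C).
    """
    if g_line < 1:
        raise ValueError("g_line must be >= 1")
    if n_per_gen < 2:
        raise ValueError("n_per_gen must be >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    spec = spec or GenomeSpec.desk_scale()
    n_cross = n_per_gen if n_cross is None else n_cross

    founders = simulate_founders(2 * n_per_gen, spec, maf_dist, rng)

    records: list[tuple[str, str, str]] = []
    line_gens: dict[str, list[list[str]]] = {}
    for line_idx, line in enumerate("AB"):
        gen0 = [f"{line}0_{k + 1:03d}" for k in range(n_per_gen)]
        for iid in gen0:
            records.append((iid, "0", "0"))
        gens = [gen0]
        for g in range(1, g_line + 1):
            prev = gens[-1]
            sires = prev[0::2]
            dams = prev[1::2]
            cohort = []
            for k in range(n_per_gen):
                iid = f"{line}{g}_{k + 1:03d}"
                records.append(
                    (
                        iid,
                        sires[int(rng.integers(len(sires)))],
                        dams[int(rng.integers(len(dams)))],
                    )
                )
                cohort.append(iid)
            gens.append(cohort)
        line_gens[line] = gens

    f1: list[str] = []
    if cross:
        sires = line_gens["A"][max(g_line - 1, 0)][0::2]
        dams = line_gens["B"][g_line][1::2]
        for k in range(n_cross):
            iid = f"C1_{k + 1:03d}"
            records.append(
                (
                    iid,
                    sires[int(rng.integers(len(sires)))],
                    dams[int(rng.integers(len(dams)))],
                )
            )
            f1.append(iid)

    pedigree = Pedigree.from_records(records)
    genotypes, truth = gene_drop(pedigree, founders, rng)

    index = {iid: k for k, iid in enumerate(genotypes.individual_ids)}

    def cohort_matrix(ids: list[str], label: str) -> GenotypeMatrix:
        g = genotypes.subset_individuals([index[i] for i in ids])
        g.population_label = label
        return g

    populations = {
        "POP_A": cohort_matrix(line_gens["A"][g_line], "POP_A"),
        "POP_B": cohort_matrix(line_gens["B"][g_line], "POP_B"),
    }
    if cross:
        populations["POP_C"] = cohort_matrix(f1, "POP_C")
    return StudyDesign(
        populations, founders.marker_map, pedigree, truth, founders, genotypes
    )
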