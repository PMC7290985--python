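"""Runs-of-homozygosity detection by a sliding-window scan.

A window of ``window_size_snp`` consecutive SNPs slides one SNP at a
time along each chromosome.  A window is called homozygous when it
contains at most ``max_het_in_window`` heterozygous and at most
``max_missing_in_window`` missing calls.  Each SNP is assigned the
proportion of homozygous windows among all windows covering it; SNPs
with proportion >= 1 - ``window_threshold`` are eligible.  Maximal runs
of eligible SNPs are split wherever two adjacent SNPs are farther apart
than ``max_gap_bp`` and the pieces are kept if they satisfy the run
constraints: minimum SNP count, minimum length, and marker density.

Segment length is ``end_bp - start_bp`` (positions of the first and last
SNP in the run), the detectRUNS convention.  Detected runs 1 Mb and
longer are binned into five length classes — 1-2, 2-4, 4-8, 8-16 and
>16 Mb — which under 1 cM = 1 Mb date the autozygosity they reflect to
roughly 50, 20, 12.5, 6 and 3 generations from the common ancestor via
E(L | g) = 100 / (2 g) Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, MarkerMap

#: Length-class labels, lower bounds in Mb (half-open bins, last unbounded).
LENGTH_CLASSES = ("1-2", "2-4", "4-8", "8-16", ">16")
_CLASS_EDGES_MB = (1.0, 2.0, 4.0, 8.0, 16.0)

#: cM per Mb used to convert segment length to generations (salmonid
#: arrays are annotated with ~1 cM ~ 1 Mb; configurable for other maps).
DEFAULT_CM_PER_MB = 1.0


@dataclass(frozen=True)
class ROHParams:
    """Detection thresholds.  Defaults follow common SNP-array practice:
    50-SNP windows, one heterozygote and five missing calls tolerated per
    window, runs >= 50 SNPs and >= 1 Mb, adjacent-SNP gaps <= 500 kb and
    at least one SNP per 50 kb."""

    min_snp: int = 50
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 500_000
    max_missing_in_window: int = 5
    max_het_in_window: int = 1
    min_density_bp_per_snp: int = 50_000
    window_size_snp: int = 50
    window_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "min_snp", "min_length_bp", "max_gap_bp", "min_density_bp_per_snp",
            "window_size_snp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_missing_in_window < 0 or self.max_het_in_window < 0:
            raise ValueError("window tolerances must be non-negative")
        if not 0.0 <= self.window_threshold < 1.0:
            raise ValueError("window_threshold must be in [0, 1)")
        if self.window_size_snp < self.max_missing_in_window + self.max_het_in_window:
            raise ValueError(
                "window_size_snp must be >= max_missing_in_window + "
                "max_het_in_window"
            )


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run of one individual on one chromosome."""

    individual_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snp: int
    length_bp: int
    length_class: str

    def __post_init__(self) -> None:
        if self.length_bp != self.end_bp - self.start_bp:
            raise ValueError("length_bp must equal end_bp - start_bp")


def classify_length(length_bp: int) -> str:
    """Length class for a detected run (half-open Mb bins, 16 Mb -> >16)."""
    mb = length_bp / 1e6
    if mb < _CLASS_EDGES_MB[0]:
        raise ValueError(
            f"segment of {mb:.3f} Mb is below the 1 Mb detection minimum"
        )
    for low, high, label in zip(
        _CLASS_EDGES_MB[:-1], _CLASS_EDGES_MB[1:], LENGTH_CLASSES[:-1]
    ):
        if low <= mb < high:
            return label
    return LENGTH_CLASSES[-1]


def generations_from_length(length_mb: float, cm_per_mb: float = DEFAULT_CM_PER_MB) -> float:
    """Generations to the common ancestor implied by an IBD segment.

    The expected length of an IBD segment around an ancestor g
    generations back is 100 / (2 g) cM; inverting at ``cm_per_mb`` cM/Mb
    gives g = 100 / (2 L).  A 1 Mb segment dates ~50 generations back, a
    4 Mb segment ~12.5.
    """
    if length_mb <= 0:
        raise ValueError("segment length must be positive")
    if cm_per_mb <= 0:
        raise ValueError("cm_per_mb must be positive")
    return 100.0 / (2.0 * length_mb * cm_per_mb)


def expected_length(generations: float, cm_per_mb: float = DEFAULT_CM_PER_MB) -> float:
    """Expected IBD segment length (Mb) around an ancestor g generations back."""
    if generations <= 0:
        raise ValueError("generations must be positive")
    if cm_per_mb <= 0:
        raise ValueError("cm_per_mb must be positive")
    return 100.0 / (2.0 * generations * cm_per_mb)


def scan_windows(calls: np.ndarray, params: ROHParams | None = None) -> np.ndarray:
    """Per-SNP homozygous-window proportion on one chromosome.

    ``calls`` is one individual's genotype vector in map order.  If the
    chromosome has fewer SNPs than the window size, the whole chromosome
    is treated as a single window.
    """
    params = params or ROHParams()
    calls = np.asarray(calls)
    n = calls.size
    if n == 0:
        return np.empty(0, dtype=float)
    w = min(params.window_size_snp, n)

    het = np.concatenate([[0], np.cumsum(calls == 1)])
    mis = np.concatenate([[0], np.cumsum(calls == MISSING)])
    het_w = het[w:] - het[:-w]
    mis_w = mis[w:] - mis[:-w]
    hom_win = (het_w <= params.max_het_in_window) & (
        mis_w <= params.max_missing_in_window
    )

    cum = np.concatenate([[0], np.cumsum(hom_win)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)          # first window start covering SNP
    hi = np.minimum(idx, n - w)              # last window start (inclusive)
    return (cum[hi + 1] - cum[lo]) / (hi - lo + 1)


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of True values."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_roh(
    g: GenotypeMatrix,
    marker_map: MarkerMap,
    params: ROHParams | None = None,
) -> list[ROHSegment]:
    """Detect ROH for every individual on every chromosome.

    Output is ordered by (individual in matrix order, chromosome in map
    order, start position) and is deterministic.
    """
    params = params or ROHParams()
    if g.n_markers != marker_map.n_markers:
        raise ValueError("genotype matrix and marker map disagree on marker count")
    blocks = marker_map.chrom_blocks()
    positions = marker_map.positions
    segments: list[ROHSegment] = []
    for i, iid in enumerate(g.individual_ids):
        for chrom, sl in blocks.items():
            calls = g.calls[i, sl]
            pos = positions[sl]
            prop = scan_windows(calls, params)
            eligible = prop >= 1.0 - params.window_threshold
            for start, end in _runs_of(eligible):
                # split the run at adjacent-SNP gaps wider than max_gap_bp
                gaps = np.diff(pos[start : end + 1])
                cut_points = np.flatnonzero(gaps > params.max_gap_bp) + start
                piece_starts = [start] + (cut_points + 1).tolist()
                piece_ends = cut_points.tolist() + [end]
                for s, e in zip(piece_starts, piece_ends):
                    n_snp = e - s + 1
                    length = int(pos[e] - pos[s])
                    if n_snp < params.min_snp:
                        continue
                    if length < params.min_length_bp:
                        continue
                    if length / n_snp > params.min_density_bp_per_snp:
                        continue
                    segments.append(
                        ROHSegment(
                            individual_id=iid,
                            chromosome=chrom,
                            start_bp=int(pos[s]),
                            end_bp=int(pos[e]),
                            n_snp=n_snp,
                            length_bp=length,
                            length_class=classify_length(length),
                        )
                    )
    return segments


def segments_to_frame(segments: Iterable[ROHSegment]) -> pd.DataFrame:
    """Tabulate segments as a BED-like frame (one row per run)."""
    segments = list(segments)
    dtypes = {
        "individual_id": str, "chromosome": str, "start_bp": np.int64,
        "end_bp": np.int64, "n_snp": np.int64, "length_bp": np.int64,
        "length_class": str,
    }
    return pd.DataFrame(
        {
            col: np.array([getattr(s, col) for s in segments], dtype=dt)
            for col, dt in dtypes.items()
        }
    )


def write_segments(
    segments: Iterable[ROHSegment],
    path,
    fmt: str = "tsv",
    population_label: str = "FAM",
) -> None:
    """Write segments as a TSV or a PLINK ``.hom``-compatible table."""
    frame = segments_to_frame(segments)
    if fmt == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif fmt == "hom":
        hom = pd.DataFrame(
            {
                "FID": population_label,
                "IID": frame["individual_id"],
                "CHR": frame["chromosome"],
                "POS1": frame["start_bp"],
                "POS2": frame["end_bp"],
                "KB": frame["length_bp"] / 1e3,
                "NSNP": frame["n_snp"],
                "DENSITY": frame["length_bp"] / frame["n_snp"] / 1e3,
            }
        )
        hom.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'tsv' or 'hom')")


def summarize_roh(
    segments: Iterable[ROHSegment],
    individual_ids: Sequence[str],
    marker_map: MarkerMap,
) -> dict[str, pd.DataFrame]:
    """Cohort summaries of detected runs.

    Returns three frames:

    ``per_class``
        one row per length class plus an ALL row: total segment count,
        mean/SD of per-individual counts over *all* individuals, the
        same over individuals carrying at least one segment of the
        class, and mean/SD segment length (Mb; absent when no segment).
    ``per_chromosome``
        mean per-individual segment count and mean segment length per
        chromosome (all individuals in the denominator).
    ``per_individual``
        segment count and summed length for every individual, zeros
        included.
    """
    individual_ids = list(individual_ids)
    n_ind = len(individual_ids)
    frame = segments_to_frame(segments)
    unknown = set(frame["individual_id"]) - set(individual_ids)
    if unknown:
        raise ValueError(f"segments reference unknown individuals: {sorted(unknown)}")

    def class_stats(sub: pd.DataFrame, label: str) -> dict:
        counts = sub.groupby("individual_id").size()
        counts_all = counts.reindex(individual_ids, fill_value=0)
        lengths_mb = sub["length_bp"] / 1e6
        return {
            "length_class": label,
            "n_segments": len(sub),
            "n_individuals": n_ind,
            "n_individuals_with_roh": int((counts_all > 0).sum()),
            "mean_count_all": counts_all.mean() if n_ind else np.nan,
            "sd_count_all": counts_all.std(ddof=1) if n_ind > 1 else np.nan,
            "mean_count_with_roh": counts.mean() if len(counts) else np.nan,
            "sd_count_with_roh": counts.std(ddof=1) if len(counts) > 1 else np.nan,
            "mean_length_mb": lengths_mb.mean() if len(sub) else np.nan,
            "sd_length_mb": lengths_mb.std(ddof=1) if len(sub) > 1 else np.nan,
        }

    per_class = pd.DataFrame(
        [class_stats(frame, "ALL")]
        + [
            class_stats(frame[frame["length_class"] == cls], cls)
            for cls in LENGTH_CLASSES
        ]
    )

    chrom_rows = []
    for chrom in marker_map.chromosomes:
        sub = frame[frame["chromosome"] == chrom]
        chrom_rows.append(
            {
                "chromosome": chrom,
                "n_segments": len(sub),
                "mean_count_per_individual": len(sub) / n_ind if n_ind else np.nan,
                "mean_length_mb": (sub["length_bp"] / 1e6).mean()
                if len(sub)
                else np.nan,
                "sd_length_mb": (sub["length_bp"] / 1e6).std(ddof=1)
                if len(sub) > 1
                else np.nan,
            }
        )
    per_chromosome = pd.DataFrame(chrom_rows)

    counts = frame.groupby("individual_id").size().reindex(
        individual_ids, fill_value=0
    )
    total_bp = (
        frame.groupby("individual_id")["length_bp"].sum().reindex(
            individual_ids, fill_value=0
        )
    )
    per_individual = pd.DataFrame(
        {
            "individual_id": individual_ids,
            "n_segments": counts.to_numpy(),
            "total_length_bp": total_bp.to_numpy(),
            "total_length_mb": total_bp.to_numpy() / 1e6,
        }
    )
    return {
        "per_class": per_class,
        "per_chromosome": per_chromosome,
        "per_individual": per_individual,
    }
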