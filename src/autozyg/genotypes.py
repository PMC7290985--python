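"""Core containers: marker map and biallelic genotype matrix.

Genotypes are coded per marker as counts of the alternate allele
(``allele_b``): 0 = homozygous for ``allele_a``, 1 = heterozygous,
2 = homozygous for ``allele_b``.  Missing calls use the sentinel
:data:`MISSING` (-1), never 0, so homozygous-reference and missing can
never be conflated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.
MISSING: int = -1

MAP_COLUMNS = ("marker_id", "chromosome", "position_bp", "allele_a", "allele_b")


def natural_key(label: str) -> tuple:
    """Sort key treating digit groups numerically (Okis2 < Okis10)."""
    return tuple(
        int(part) if part.isdigit() else part
        for part in re.split(r"(\d+)", str(label))
    )


@dataclass(frozen=True)
class MarkerMap:
    """Per-marker coordinates and allele labels, sorted genome-wide.

    The table is always held sorted by chromosome (natural label order)
    and, within a chromosome, by strictly increasing base-pair position;
    markers of one chromosome therefore occupy one contiguous block.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        tab = self.table
        missing_cols = [c for c in MAP_COLUMNS if c not in tab.columns]
        if missing_cols:
            raise ValueError(f"marker map missing columns: {missing_cols}")
        tab = tab.loc[:, list(MAP_COLUMNS)].reset_index(drop=True)
        tab["marker_id"] = tab["marker_id"].astype(str)
        tab["chromosome"] = tab["chromosome"].astype(str)
        tab["position_bp"] = tab["position_bp"].astype(np.int64)
        tab["allele_a"] = tab["allele_a"].astype(str)
        tab["allele_b"] = tab["allele_b"].astype(str)
        order = sorted(
            range(len(tab)),
            key=lambda i: (
                natural_key(tab["chromosome"].iat[i]),
                tab["position_bp"].iat[i],
            ),
        )
        if order != list(range(len(tab))):
            tab = tab.iloc[order].reset_index(drop=True)
        if tab["marker_id"].duplicated().any():
            dup = tab["marker_id"][tab["marker_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        if (tab["position_bp"] < 1).any():
            raise ValueError("marker positions must be >= 1 (1-based)")
        for chrom, sub in tab.groupby("chromosome", sort=False):
            if (np.diff(sub["position_bp"].to_numpy()) <= 0).any():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        object.__setattr__(self, "table", tab)

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        marker_id: Sequence[str],
        chromosome: Sequence[str],
        position_bp: Sequence[int],
        allele_a: Sequence[str] | None = None,
        allele_b: Sequence[str] | None = None,
    ) -> "MarkerMap":
        n = len(marker_id)
        return cls(
            pd.DataFrame(
                {
                    "marker_id": list(marker_id),
                    "chromosome": list(chromosome),
                    "position_bp": list(position_bp),
                    "allele_a": list(allele_a) if allele_a is not None else ["A"] * n,
                    "allele_b": list(allele_b) if allele_b is not None else ["B"] * n,
                }
            )
        )

    # -- basic accessors ------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy()

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in natural order."""
        seen: dict[str, None] = {}
        for c in self.table["chromosome"]:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_blocks(self) -> dict[str, slice]:
        """Map chromosome label -> contiguous marker-index slice."""
        blocks: dict[str, slice] = {}
        chroms = self.table["chromosome"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                blocks[chroms[start]] = slice(start, i)
                start = i
        return blocks

    def chrom_spans_bp(self) -> dict[str, int]:
        """Per chromosome: last minus first marker position (panel span)."""
        pos = self.positions
        return {
            c: int(pos[sl][-1] - pos[sl][0]) for c, sl in self.chrom_blocks().items()
        }

    @property
    def l_auto_bp(self) -> int:
        """Genome span covered by the panel (sum of per-chromosome spans)."""
        return int(sum(self.chrom_spans_bp().values()))

    def subset(self, index: np.ndarray | Sequence[int]) -> "MarkerMap":
        return MarkerMap(self.table.iloc[np.asarray(index)].reset_index(drop=True))

    def indexer(self, marker_ids: Sequence[str]) -> np.ndarray:
        """Positional indices of *marker_ids* in this map (order preserved)."""
        lookup = {m: i for i, m in enumerate(self.marker_ids)}
        try:
            return np.array([lookup[m] for m in marker_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"marker {exc.args[0]!r} not in map") from None


@dataclass
class GenotypeMatrix:
    """Individuals x markers genotype calls (0/1/2, MISSING = -1)."""

    individual_ids: list[str]
    calls: np.ndarray = field(repr=False)
    population_label: str = ""

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        calls = np.asarray(self.calls)
        if calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x markers)")
        if calls.shape[0] != len(self.individual_ids):
            raise ValueError(
                f"{len(self.individual_ids)} individual ids but "
                f"{calls.shape[0]} call rows"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            seen: set[str] = set()
            dup = next(i for i in self.individual_ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate individual id {dup!r}")
        calls = calls.astype(np.int8, copy=False)
        bad = ~np.isin(calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError(
                f"invalid genotype code {calls[bad].flat[0]} "
                "(expected 0, 1, 2 or MISSING)"
            )
        self.calls = calls

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def subset_individuals(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(index)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in idx],
            self.calls[idx],
            self.population_label,
        )

    def subset_markers(self, index: Sequence[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.individual_ids),
            self.calls[:, np.asarray(index)],
            self.population_label,
        )

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele (allele_b) frequency per marker.

        Computed on non-missing calls only; all-missing markers give NaN.
        """
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def call_rate(self, axis: str = "marker") -> np.ndarray:
        """Fraction of non-missing calls per marker or per individual."""
        obs = self.calls != MISSING
        if axis == "marker":
            return obs.mean(axis=0)
        if axis == "individual":
            return obs.mean(axis=1)
        raise ValueError("axis must be 'marker' or 'individual'")

    def genotype_counts(self) -> np.ndarray:
        """Per-marker (n_hom_a, n_het, n_hom_b) counts, shape (m, 3)."""
        return np.stack(
            [(self.calls == c).sum(axis=0) for c in (0, 1, 2)], axis=1
        )
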