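"""PLINK text (PED/MAP) and binary (BED/BIM/FAM, v1.9 SNP-major) I/O.

Both dialects are read into a :class:`~autozyg.genotypes.GenotypeMatrix`
plus :class:`~autozyg.genotypes.MarkerMap`.  Marker order is the MAP/BIM
order after the per-chromosome natural sort the map enforces.

Allele polarity: for BED the BIM file stores both alleles, so the 0/2
coding round-trips exactly.  A PED/MAP pair does not record allele
labels, so on read ``allele_a`` is the first allele observed in file
order at each marker; pass ``map_hint`` (a map carrying allele labels,
e.g. the one returned by :func:`write_plink`) to pin polarity instead.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, MarkerMap

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"
# 2-bit BED code -> internal call: 00 hom A1, 01 missing, 10 het, 11 hom A2
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0, 1: 2, 2: 3, MISSING: 1}


def read_plink(
    path_prefix: str | os.PathLike,
    dialect: str = "ped",
    population_label: str | None = None,
    map_hint: MarkerMap | None = None,
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a PLINK fileset ``prefix.{ped,map}`` or ``prefix.{bed,bim,fam}``."""
    prefix = Path(path_prefix)
    label = population_label if population_label is not None else prefix.name
    if dialect == "ped":
        return _read_ped_map(prefix, label, map_hint)
    if dialect == "bed":
        return _read_bed(prefix, label)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'ped' or 'bed')")


def write_plink(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    path_prefix: str | os.PathLike,
    dialect: str = "ped",
) -> None:
    """Write ``prefix.{ped,map}`` or ``prefix.{bed,bim,fam}``."""
    if genotypes.n_markers != marker_map.n_markers:
        raise ValueError("genotype matrix and marker map disagree on marker count")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "ped":
        _write_ped_map(genotypes, marker_map, prefix)
    elif dialect == "bed":
        _write_bed(genotypes, marker_map, prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'ped' or 'bed')")


# ---------------------------------------------------------------------------
# text dialect
# ---------------------------------------------------------------------------

def _read_map_file(path: Path, with_alleles: bool) -> pd.DataFrame:
    ncol = 6 if with_alleles else 4
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != ncol:
                raise ValueError(
                    f"{path.name}:{lineno}: expected {ncol} fields, got {len(fields)}"
                )
            rows.append(fields)
    if not rows:
        raise ValueError(f"{path.name}: no markers")
    cols = ["chromosome", "marker_id", "cm", "position_bp"]
    if with_alleles:
        cols += ["allele_a", "allele_b"]
    frame = pd.DataFrame(rows, columns=cols)
    frame["position_bp"] = frame["position_bp"].astype(np.int64)
    return frame


def _read_ped_map(
    prefix: Path, label: str, map_hint: MarkerMap | None
) -> tuple[GenotypeMatrix, MarkerMap]:
    raw_map = _read_map_file(prefix.with_suffix(".map"), with_alleles=False)
    m = len(raw_map)

    ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"{prefix.name}.ped:{lineno}: expected {6 + 2 * m} fields "
                    f"for {m} markers, got {len(fields)}"
                )
            iid = fields[1]
            if iid in ids:
                raise ValueError(
                    f"{prefix.name}.ped:{lineno}: duplicate individual id {iid!r}"
                )
            ids.append(iid)
            allele_rows.append(fields[6:])
    if not ids:
        raise ValueError(f"{prefix.name}.ped: no individuals")

    # (n, m, 2) array of allele strings, file order preserved
    alleles = np.array(allele_rows, dtype=object).reshape(len(ids), m, 2)

    if map_hint is not None:
        if list(map_hint.marker_ids) != list(raw_map["marker_id"]):
            # hint is in sorted order; realign to the raw MAP order
            hint = map_hint.table.set_index("marker_id")
            try:
                hint = hint.loc[raw_map["marker_id"]]
            except KeyError as exc:
                raise ValueError(f"map_hint lacks marker {exc.args[0]!r}") from None
        else:
            hint = map_hint.table.set_index("marker_id")
        allele_a = hint["allele_a"].to_numpy()
        allele_b = hint["allele_b"].to_numpy()
    else:
        allele_a = np.empty(m, dtype=object)
        allele_b = np.empty(m, dtype=object)
        allele_a[:] = "0"
        allele_b[:] = "0"

    calls = np.full((len(ids), m), MISSING, dtype=np.int8)
    for j in range(m):
        col = alleles[:, j, :]
        obs = (col[:, 0] != "0") & (col[:, 1] != "0")
        seen: list[str] = []
        for val in col[obs].ravel():
            if val not in seen:
                seen.append(val)
        if len(seen) > 2:
            raise ValueError(
                f"marker {raw_map['marker_id'].iat[j]!r}: more than two alleles {seen}"
            )
        if map_hint is None:
            if seen:
                allele_a[j] = seen[0]
                allele_b[j] = seen[1] if len(seen) > 1 else "0"
        else:
            known = {allele_a[j], allele_b[j]}
            stray = [s for s in seen if s not in known]
            if stray:
                raise ValueError(
                    f"marker {raw_map['marker_id'].iat[j]!r}: allele {stray[0]!r} "
                    "not in map_hint"
                )
        b = allele_b[j]
        calls[obs, j] = (col[obs, 0] == b).astype(np.int8) + (
            col[obs, 1] == b
        ).astype(np.int8)

    mmap = MarkerMap.from_arrays(
        raw_map["marker_id"],
        raw_map["chromosome"],
        raw_map["position_bp"],
        allele_a,
        allele_b,
    )
    # reorder calls to the map's sorted marker order
    order = {mid: k for k, mid in enumerate(raw_map["marker_id"])}
    calls = calls[:, [order[mid] for mid in mmap.marker_ids]]
    return GenotypeMatrix(ids, calls, label), mmap


def _write_ped_map(g: GenotypeMatrix, mmap: MarkerMap, prefix: Path) -> None:
    tab = mmap.table
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in tab.iterrows():
            fh.write(
                f"{row.chromosome}\t{row.marker_id}\t0\t{row.position_bp}\n"
            )
    a = tab["allele_a"].to_numpy(dtype=object)
    b = tab["allele_b"].to_numpy(dtype=object)
    calls = g.calls
    first = np.where(calls == 2, b, a)
    second = np.where(calls == 0, a, b)
    missing = calls == MISSING
    first[missing] = "0"
    second[missing] = "0"
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(g.individual_ids):
            pairs = " ".join(
                f"{x} {y}" for x, y in zip(first[i], second[i])
            )
            fam = g.population_label or "FAM"
            fh.write(f"{fam} {iid} 0 0 0 -9 {pairs}\n")


# ---------------------------------------------------------------------------
# binary dialect
# ---------------------------------------------------------------------------

def _read_bed(prefix: Path, label: str) -> tuple[GenotypeMatrix, MarkerMap]:
    bim = _read_map_file(prefix.with_suffix(".bim"), with_alleles=True)
    fam_ids: list[str] = []
    with open(prefix.with_suffix(".fam")) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{prefix.name}.fam:{lineno}: too few fields")
            if fields[1] in fam_ids:
                raise ValueError(
                    f"{prefix.name}.fam:{lineno}: duplicate individual id "
                    f"{fields[1]!r}"
                )
            fam_ids.append(fields[1])
    n, m = len(fam_ids), len(bim)

    data = Path(prefix.with_suffix(".bed")).read_bytes()
    if data[:2] != _BED_MAGIC:
        raise ValueError(f"{prefix.name}.bed: bad magic bytes")
    if data[2:3] != _BED_SNP_MAJOR:
        raise ValueError(f"{prefix.name}.bed: not SNP-major (mode byte != 0x01)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(data, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_snp:
        raise ValueError(
            f"{prefix.name}.bed: expected {m * bytes_per_snp} data bytes, "
            f"got {body.size}"
        )
    body = body.reshape(m, bytes_per_snp)
    # expand each byte into four 2-bit codes (individuals packed LSB-first)
    two_bit = (body[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 0b11
    codes = two_bit.reshape(m, bytes_per_snp * 4)[:, :n]
    calls = _BED_DECODE[codes].T.copy()  # -> (n, m)

    mmap = MarkerMap.from_arrays(
        bim["marker_id"], bim["chromosome"], bim["position_bp"],
        bim["allele_a"], bim["allele_b"],
    )
    order = {mid: k for k, mid in enumerate(bim["marker_id"])}
    calls = calls[:, [order[mid] for mid in mmap.marker_ids]]
    return GenotypeMatrix(fam_ids, calls, label), mmap


def _write_bed(g: GenotypeMatrix, mmap: MarkerMap, prefix: Path) -> None:
    tab = mmap.table
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, row in tab.iterrows():
            fh.write(
                f"{row.chromosome}\t{row.marker_id}\t0\t{row.position_bp}"
                f"\t{row.allele_a}\t{row.allele_b}\n"
            )
    fam = g.population_label or "FAM"
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for iid in g.individual_ids:
            fh.write(f"{fam} {iid} 0 0 0 -9\n")

    n, m = g.n_individuals, g.n_markers
    bytes_per_snp = (n + 3) // 4
    enc = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    snp_major = g.calls.T
    for call, code in _BED_ENCODE.items():
        enc[:, :n][snp_major == call] = code
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (enc.reshape(m, bytes_per_snp, 4) << shifts).sum(
        axis=2, dtype=np.uint16
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        fh.write(packed.tobytes())
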