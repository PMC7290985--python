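"""End-to-end orchestration: QC -> ROH -> inbreeding -> structure -> reports.

One declarative :class:`RunConfig` drives a deterministic run whose
outputs land in a single directory: QC reports, ROH segment tables and
summaries, per-individual inbreeding estimates with correlations and
group tests, and PCA scores.  The configuration used is serialised
verbatim next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inbreeding as ib
from .genotypes import GenotypeMatrix, MarkerMap
from .pedigree import f_ped, read_pedigree
from .plink import read_plink
from .qc import QCReport, intersect_markers, qc_filter
from .roh import ROHParams, detect_roh, segments_to_frame, summarize_roh, write_segments
from .structure import pca_genotypes

logger = logging.getLogger("autozyg")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, validated up front."""

    populations: dict[str, dict]  # name -> {prefix, dialect}
    output_dir: str
    pedigree_path: str | None = None
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    call_rate_min: float = 0.90
    roh: ROHParams = field(default_factory=ROHParams)
    l_auto_mode: str = "panel"  # or "fixed"
    l_auto_fixed_bp: int = ib.DEFAULT_L_AUTO_BP
    grm_mode: str = "gjj_minus_1"
    n_pca_components: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("config lists no populations")
        for name, entry in self.populations.items():
            if "prefix" not in entry:
                raise ValueError(f"population {name!r} has no 'prefix'")
            entry.setdefault("dialect", "ped")
            if entry["dialect"] not in ("ped", "bed"):
                raise ValueError(f"population {name!r}: bad dialect")
        if self.l_auto_mode not in ("panel", "fixed"):
            raise ValueError("l_auto_mode must be 'panel' or 'fixed'")
        if self.grm_mode not in ib.GRM_MODES:
            raise ValueError(f"grm_mode must be one of {ib.GRM_MODES}")
        if not isinstance(self.roh, ROHParams):
            self.roh = ROHParams(**self.roh)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _write_tsv(frame: pd.DataFrame, path: Path, float_format: str = "%.10g") -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the in-memory report bundle.

    Output files (all TSV/JSON) are written under ``config.output_dir``.
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    bundle: dict = {}
    try:
        # ---- load + QC per population -------------------------------
        stage = "qc"
        pops: list[tuple[GenotypeMatrix, MarkerMap]] = []
        reports: dict[str, QCReport] = {}
        try:
            for name, entry in config.populations.items():
                g, mmap = read_plink(
                    entry["prefix"], entry["dialect"], population_label=name
                )
                logger.info(
                    "loaded %s: %d individuals x %d markers",
                    name, g.n_individuals, g.n_markers,
                )
                g, mmap, report = qc_filter(
                    g, mmap,
                    maf_min=config.maf_min,
                    hwe_p_min=config.hwe_p_min,
                    call_rate_min=config.call_rate_min,
                )
                logger.info(
                    "QC %s: retained %d markers (thresholds maf>=%g, "
                    "hwe_p>=%g, call_rate>=%g)",
                    name, report.n_retained, config.maf_min,
                    config.hwe_p_min, config.call_rate_min,
                )
                pops.append((g, mmap))
                reports[name] = report
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        # ---- intersect ----------------------------------------------
        stage = "intersect"
        try:
            if len(pops) >= 2:
                pops = intersect_markers(pops)
                for (g, mmap) in pops:
                    reports[g.population_label].apply_intersection(mmap.n_markers)
            for report in reports.values():
                report.check()
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        shared_map = pops[0][1]
        for name, report in reports.items():
            (outdir / f"qc_{name}.json").write_text(report.to_json() + "\n")
            (outdir / f"qc_{name}.txt").write_text(report.to_text() + "\n")
        bundle["qc"] = reports

        # ---- ROH per population -------------------------------------
        stage = "roh"
        try:
            l_auto_bp = ib.l_auto(
                shared_map, config.l_auto_mode, config.l_auto_fixed_bp
            )
            segments = {}
            summaries = {}
            for g, mmap in pops:
                segs = detect_roh(g, mmap, config.roh)
                segments[g.population_label] = segs
                summaries[g.population_label] = summarize_roh(
                    segs, g.individual_ids, mmap
                )
                write_segments(
                    segs, outdir / f"roh_segments_{g.population_label}.tsv"
                )
                write_segments(
                    segs,
                    outdir / f"roh_segments_{g.population_label}.hom",
                    fmt="hom",
                    population_label=g.population_label,
                )
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        per_class = pd.concat(
            [
                s["per_class"].assign(population=name)
                for name, s in summaries.items()
            ],
            ignore_index=True,
        )
        per_chrom = pd.concat(
            [
                s["per_chromosome"].assign(population=name)
                for name, s in summaries.items()
            ],
            ignore_index=True,
        )
        per_ind = pd.concat(
            [
                s["per_individual"].assign(population=name)
                for name, s in summaries.items()
            ],
            ignore_index=True,
        )
        _write_tsv(per_class, outdir / "roh_summary_per_class.tsv")
        _write_tsv(per_chrom, outdir / "roh_summary_per_chromosome.tsv")
        _write_tsv(per_ind, outdir / "roh_per_individual.tsv")
        bundle["roh"] = {"segments": segments, "summaries": summaries}

        # ---- pedigree -----------------------------------------------
        stage = "pedigree"
        fped = None
        try:
            if config.pedigree_path:
                ped = read_pedigree(config.pedigree_path)
                fped = f_ped(ped)
                fped.rename("f_ped").reset_index().to_csv(
                    outdir / "f_ped.tsv", sep="\t", index=False,
                    float_format="%.10g",
                )
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        # ---- inbreeding ---------------------------------------------
        stage = "inbreeding"
        try:
            tables = []
            for g, mmap in pops:
                tables.append(
                    ib.inbreeding_table(
                        g, mmap, detect_roh(g, mmap, config.roh),
                        l_auto_bp=l_auto_bp,
                        grm_mode=config.grm_mode,
                        f_ped_values=fped,
                    )
                )
            table = pd.concat(tables, ignore_index=True)
            comparison = ib.compare_estimators(table)
            per_chrom_froh = pd.concat(
                [
                    ib.f_roh_per_chromosome(
                        segments[g.population_label], g.individual_ids, mmap
                    ).assign(population=g.population_label)
                    for g, mmap in pops
                ],
                ignore_index=True,
            )
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        _write_tsv(table, outdir / "inbreeding_table.tsv")
        _write_tsv(comparison["correlations"], outdir / "correlations.tsv")
        _write_tsv(comparison["group_tests"], outdir / "inbreeding_summary.tsv")
        _write_tsv(per_chrom_froh, outdir / "f_roh_per_chromosome.tsv")
        meta = {
            "l_auto_mode": config.l_auto_mode,
            "l_auto_bp": int(l_auto_bp),
            "grm_mode": config.grm_mode,
        }
        (outdir / "inbreeding_meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )
        bundle["inbreeding"] = {"table": table, **comparison, "meta": meta}

        # ---- structure ----------------------------------------------
        stage = "pca"
        try:
            merged = GenotypeMatrix(
                [i for g, _ in pops for i in g.individual_ids],
                np.vstack([g.calls for g, _ in pops]),
                "ALL",
            )
            pca = pca_genotypes(merged, config.n_pca_components)
            scores = pca.scores.reset_index()
            scores.insert(
                1,
                "population",
                [g.population_label for g, _ in pops for _ in g.individual_ids],
            )
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        _write_tsv(scores, outdir / "pca_scores.tsv")
        _write_tsv(
            pd.DataFrame(
                {
                    "component": [f"PC{k + 1}" for k in range(pca.n_components)],
                    "eigenvalue": pca.eigenvalues,
                    "proportion_variance": pca.proportion_variance,
                }
            ),
            outdir / "pca_eigenvalues.tsv",
        )
        bundle["pca"] = pca
        logger.info("pipeline complete: outputs in %s", outdir)
        return bundle
    finally:
        logger.removeHandler(handler)
        handler.close()
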