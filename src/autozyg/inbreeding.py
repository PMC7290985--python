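"""Genomic inbreeding coefficients and estimator comparison.

Three genomic estimators are provided for each individual j:

``F_ROH``   fraction of the autosomal genome covered by runs of
            homozygosity, L_ROH / L_AUTO, optionally restricted to runs
            at least a minimum length.
``F_HOM``   excess homozygosity, (O_hom - E_hom) / (N - E_hom), with the
            Hardy-Weinberg expectation E_hom computed from in-sample
            allele frequencies.
``F_GRM``   read off the diagonal of the VanRaden genomic relationship
            matrix G = Z Z' / (2 sum p_i (1 - p_i)), where Z holds the
            2p-centred genotype dosages.  E[G_jj] = 1 + F_j, so the
            default mode reports G_jj - 1; a ``two_gjj_minus_1`` mode
            reporting 2 G_jj - 1 is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix, MarkerMap
from .roh import ROHSegment, segments_to_frame

#: Genome length (bp) covered by the 200K coho salmon array, the fixed
#: denominator mode for F_ROH (1685.79 Mb).
DEFAULT_L_AUTO_BP = 1_685_790_000

GRM_MODES = ("gjj_minus_1", "two_gjj_minus_1")

F_ROH_THRESHOLDS_MB = (1, 2, 4, 8, 16)


def l_auto(
    marker_map: MarkerMap | None = None,
    mode: str = "panel",
    fixed_bp: int = DEFAULT_L_AUTO_BP,
) -> int:
    """Autosomal genome length used as the F_ROH denominator.

    ``panel`` sums per-chromosome spans of the marker map (last minus
    first SNP); ``fixed`` returns ``fixed_bp``.
    """
    if mode == "fixed":
        return int(fixed_bp)
    if mode == "panel":
        if marker_map is None:
            raise ValueError("panel mode needs a marker map")
        return marker_map.l_auto_bp
    raise ValueError(f"unknown l_auto mode {mode!r}")


def _check_non_overlapping(frame: pd.DataFrame) -> None:
    for (iid, chrom), sub in frame.groupby(["individual_id", "chromosome"]):
        sub = sub.sort_values("start_bp")
        if (sub["start_bp"].to_numpy()[1:] < sub["end_bp"].to_numpy()[:-1]).any():
            raise ValueError(
                f"overlapping segments for individual {iid!r} on {chrom}"
            )


def f_roh(
    segments: Iterable[ROHSegment] | pd.DataFrame,
    l_auto_bp: int,
    min_length_mb: float = 1.0,
) -> float:
    """F_ROH for one individual: summed run length over genome length.

    Only runs at least ``min_length_mb`` long contribute (cumulative
    threshold, not a disjoint bin).
    """
    if l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    frame = (
        segments if isinstance(segments, pd.DataFrame) else segments_to_frame(segments)
    )
    if frame["individual_id"].nunique() > 1:
        raise ValueError("f_roh expects segments of a single individual")
    _check_non_overlapping(frame)
    kept = frame[frame["length_bp"] >= min_length_mb * 1e6]
    return float(kept["length_bp"].sum() / l_auto_bp)


def f_roh_table(
    segments: Iterable[ROHSegment] | pd.DataFrame,
    individual_ids: Sequence[str],
    l_auto_bp: int,
    thresholds_mb: Sequence[float] = F_ROH_THRESHOLDS_MB,
    disjoint_bins: bool = False,
) -> pd.DataFrame:
    """Per-individual F_ROH at each length threshold plus genome-wide.

    Default rows are cumulative minimum-length thresholds (the >=1 Mb
    column equals the ALL column); ``disjoint_bins`` switches to
    contributions from each [low, next) class only.
    """
    if l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    frame = (
        segments if isinstance(segments, pd.DataFrame) else segments_to_frame(segments)
    )
    _check_non_overlapping(frame)
    individual_ids = list(individual_ids)
    lengths = frame["length_bp"].to_numpy()
    out = pd.DataFrame({"individual_id": individual_ids}).set_index(
        "individual_id", drop=False
    )
    total = frame.groupby("individual_id")["length_bp"].sum()
    out["f_roh_all"] = total.reindex(individual_ids, fill_value=0) / l_auto_bp
    edges = list(thresholds_mb) + [np.inf]
    for k, thr in enumerate(thresholds_mb):
        if disjoint_bins:
            mask = (lengths >= thr * 1e6) & (lengths < edges[k + 1] * 1e6)
            col = f"f_roh_bin_{thr:g}mb"
        else:
            mask = lengths >= thr * 1e6
            col = f"f_roh_ge_{thr:g}mb"
        s = frame[mask].groupby("individual_id")["length_bp"].sum()
        out[col] = s.reindex(individual_ids, fill_value=0) / l_auto_bp
    return out.reset_index(drop=True)


def f_roh_per_chromosome(
    segments: Iterable[ROHSegment] | pd.DataFrame,
    individual_ids: Sequence[str],
    marker_map: MarkerMap,
) -> pd.DataFrame:
    """Per-individual, per-chromosome F_ROH (chromosome panel span as
    denominator — a fixed genome-wide constant has no per-chromosome
    analogue)."""
    frame = (
        segments if isinstance(segments, pd.DataFrame) else segments_to_frame(segments)
    )
    _check_non_overlapping(frame)
    spans = marker_map.chrom_spans_bp()
    out = pd.DataFrame({"individual_id": list(individual_ids)})
    for chrom in marker_map.chromosomes:
        sub = frame[frame["chromosome"] == chrom]
        s = sub.groupby("individual_id")["length_bp"].sum()
        span = spans[chrom]
        out[chrom] = (
            s.reindex(list(individual_ids), fill_value=0).to_numpy() / span
            if span > 0
            else np.nan
        )
    return out


def f_hom(
    g: GenotypeMatrix, allele_frequencies: np.ndarray | None = None
) -> pd.Series:
    """Excess-homozygosity inbreeding coefficient per individual.

    O_hom and E_hom are computed over each individual's non-missing
    markers; frequencies default to the in-sample estimates.  When
    N = E_hom for an individual (only fixed markers observed) the value
    is undefined and reported as NaN.
    """
    p = (
        g.allele_frequencies()
        if allele_frequencies is None
        else np.asarray(allele_frequencies, dtype=float)
    )
    if p.shape != (g.n_markers,):
        raise ValueError("allele_frequencies length must match marker count")
    obs = g.calls != MISSING
    e_marker = 1.0 - 2.0 * p * (1.0 - p)  # P(homozygous | HWE)
    o_hom = (obs & (g.calls != 1)).sum(axis=1)
    e_hom = np.where(obs, e_marker, 0.0).sum(axis=1)
    n = obs.sum(axis=1)
    denom = n - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(
            np.abs(denom) > 1e-12, (o_hom - e_hom) / denom, np.nan
        )
    return pd.Series(values, index=pd.Index(g.individual_ids, name="individual_id"))


@dataclass
class GRM:
    """VanRaden genomic relationship matrix over a cohort."""

    matrix: np.ndarray = field(repr=False)
    allele_frequencies: np.ndarray = field(repr=False)
    individual_ids: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("GRM must be square")
        if m.shape[0] != len(self.individual_ids):
            raise ValueError("GRM dimension must match individual count")
        self.matrix = m

    def to_gcta_text(self, path) -> None:
        """Write lower triangle in the GCTA .grm text layout (i j n g)."""
        n_markers = self.allele_frequencies.size
        with open(path, "w") as fh:
            for i in range(len(self.individual_ids)):
                for j in range(i + 1):
                    fh.write(f"{i + 1}\t{j + 1}\t{n_markers}\t{self.matrix[i, j]:.8g}\n")


def build_grm(
    g: GenotypeMatrix, allele_frequencies: np.ndarray | None = None
) -> GRM:
    """G = Z Z' / (2 sum p (1 - p)); Z holds dosages centred by 2p.

    Missing calls contribute 0 after centring (mean imputation).  Input
    must contain at least one polymorphic marker, else the denominator
    vanishes.
    """
    p = (
        g.allele_frequencies()
        if allele_frequencies is None
        else np.asarray(allele_frequencies, dtype=float)
    )
    if p.shape != (g.n_markers,):
        raise ValueError("allele_frequencies length must match marker count")
    p_safe = np.nan_to_num(p, nan=0.0)
    denom = 2.0 * float(np.sum(p_safe * (1.0 - p_safe)))
    if denom <= 0.0:
        raise ValueError("no polymorphic markers: GRM denominator is zero")
    z = np.where(g.calls != MISSING, g.calls, 2.0 * p_safe) - 2.0 * p_safe
    matrix = (z @ z.T) / denom
    return GRM(matrix, p_safe, list(g.individual_ids))


def f_grm(grm: GRM, mode: str = "gjj_minus_1") -> pd.Series:
    """Inbreeding from the GRM diagonal.

    ``gjj_minus_1`` (default) uses E[G_jj] = 1 + F; ``two_gjj_minus_1``
    reports 2 G_jj - 1 instead.
    """
    diag = np.diagonal(grm.matrix)
    if mode == "gjj_minus_1":
        values = diag - 1.0
    elif mode == "two_gjj_minus_1":
        values = 2.0 * diag - 1.0
    else:
        raise ValueError(f"unknown f_grm mode {mode!r} (expected one of {GRM_MODES})")
    return pd.Series(
        values, index=pd.Index(grm.individual_ids, name="individual_id")
    )


def inbreeding_table(
    g: GenotypeMatrix,
    marker_map: MarkerMap,
    segments: Iterable[ROHSegment] | pd.DataFrame,
    l_auto_bp: int | None = None,
    grm_mode: str = "gjj_minus_1",
    f_ped_values: Mapping[str, float] | pd.Series | None = None,
    allele_frequencies: np.ndarray | None = None,
) -> pd.DataFrame:
    """Join every estimator into one per-individual table.

    ``l_auto_bp`` defaults to the panel span of ``marker_map``;
    individuals absent from ``f_ped_values`` get NaN.
    """
    if l_auto_bp is None:
        l_auto_bp = marker_map.l_auto_bp
    table = f_roh_table(segments, g.individual_ids, l_auto_bp)
    table["f_hom"] = f_hom(g, allele_frequencies).to_numpy()
    table["f_grm"] = f_grm(build_grm(g, allele_frequencies), grm_mode).to_numpy()
    if f_ped_values is not None:
        fped = pd.Series(f_ped_values)
        table["f_ped"] = fped.reindex(g.individual_ids).to_numpy()
    table.insert(0, "population", g.population_label)
    return table


# ---------------------------------------------------------------------------
# estimator comparison
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3 or x.min() == x.max() or y.min() == y.max():
        return np.nan, np.nan, int(x.size)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def correlation_table(
    table: pd.DataFrame,
    estimators: Sequence[str] | None = None,
    group_col: str = "population",
) -> pd.DataFrame:
    """Pearson r (with two-sided p) for every estimator pair, within each
    population and pooled (group label ``ALL``).

    Zero-variance estimators and groups with < 3 individuals give NaN
    (undefined, not zero).
    """
    if estimators is None:
        estimators = [
            c
            for c in table.columns
            if c.startswith(("f_roh", "f_hom", "f_grm", "f_ped"))
        ]
    groups: list[tuple[str, pd.DataFrame]] = [("ALL", table)]
    if group_col in table.columns:
        groups += [(str(k), sub) for k, sub in table.groupby(group_col)]
    rows = []
    for label, sub in groups:
        for a_i, a in enumerate(estimators):
            for b in estimators[a_i:]:
                r, p, n = _pearson(
                    sub[a].to_numpy(dtype=float), sub[b].to_numpy(dtype=float)
                )
                rows.append(
                    {"group": label, "estimator_a": a, "estimator_b": b,
                     "r": r, "p_value": p, "n": n}
                )
    return pd.DataFrame(rows)


def _compact_letters(
    groups: Sequence[str],
    means: Mapping[str, float],
    not_significant: set[tuple[str, str]],
) -> dict[str, str]:
    """Compact letter display from the graph of non-significant pairs.

    Letters are the maximal cliques of the graph, lettered in order of
    their best (largest) group mean; groups sharing a letter do not
    differ significantly.
    """
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(groups)
    graph.add_edges_from(not_significant)
    cliques = list(nx.find_cliques(graph))
    order = sorted(groups, key=lambda g: -means[g])
    rank = {g: i for i, g in enumerate(order)}
    cliques.sort(key=lambda c: min(rank[g] for g in c))
    letters: dict[str, list[str]] = {g: [] for g in groups}
    for k, clique in enumerate(cliques):
        letter = chr(ord("a") + k)
        for g in clique:
            letters[g].append(letter)
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def group_difference_table(
    table: pd.DataFrame,
    estimators: Sequence[str] | None = None,
    group_col: str = "population",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Welch t-tests across populations per estimator, with a
    compact letter display (shared letter = not significantly different
    at ``alpha``; no multiplicity correction).

    Pairs where the test is undefined (a group with < 2 finite values)
    are treated as not significantly different.
    """
    if estimators is None:
        estimators = [
            c
            for c in table.columns
            if c.startswith(("f_roh", "f_hom", "f_grm", "f_ped"))
        ]
    pops = [str(k) for k in table[group_col].unique()]
    rows = []
    for est in estimators:
        data = {
            p: table.loc[table[group_col].astype(str) == p, est]
            .to_numpy(dtype=float)
            for p in pops
        }
        data = {p: v[np.isfinite(v)] for p, v in data.items()}
        means = {p: (v.mean() if v.size else np.nan) for p, v in data.items()}
        ns_pairs: set[tuple[str, str]] = set()
        pvals = {}
        for i, p1 in enumerate(pops):
            for p2 in pops[i + 1 :]:
                if data[p1].size < 2 or data[p2].size < 2:
                    pval = np.nan
                else:
                    pval = float(
                        stats.ttest_ind(data[p1], data[p2], equal_var=False).pvalue
                    )
                pvals[(p1, p2)] = pval
                if not (pval < alpha):  # NaN -> not significant
                    ns_pairs.add((p1, p2))
        letters = _compact_letters(pops, means, ns_pairs)
        for p in pops:
            rows.append(
                {
                    "estimator": est,
                    group_col: p,
                    "n": int(data[p].size),
                    "mean": means[p],
                    "sd": float(np.std(data[p], ddof=1))
                    if data[p].size > 1
                    else np.nan,
                    "letters": letters[p],
                }
            )
    return pd.DataFrame(rows)


def compare_estimators(
    table: pd.DataFrame,
    estimators: Sequence[str] | None = None,
    group_col: str = "population",
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Correlation matrix (within and pooled) plus group tests."""
    return {
        "correlations": correlation_table(table, estimators, group_col),
        "group_tests": group_difference_table(table, estimators, group_col, alpha),
    }
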