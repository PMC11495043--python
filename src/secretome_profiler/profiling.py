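"""Per-MAG profiles and cohort statistics.

Aggregates per-protein results into per-genome count vectors (compartments,
enzyme classes, heme classes), applies the cohort-level conventions —
"especially high" means a count more than two sample standard deviations above
the cohort mean (strict >), "abundant" means mean relative abundance above
0.1% (strict >) — and implements the orthogroup presentation layer: count
matrix, ranking by summed counts, and the clustering recipe (rows centered and
unit-variance scaled, correlation distance, average linkage) with Newick
export.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .config import PipelineConfig
from .errors import IntegrityError, UsageError
from .records import (
    AbundanceRecord,
    CompartmentAssignment,
    EnzymeCall,
    EnzymeClass,
    HemeProfile,
    Location,
    OrthogroupMembership,
)

#: order of the count columns in profiles
COMPARTMENT_METRICS = ("EC", "OM", "CW", "PP", "CM", "CY", "UNK", "UNK_SP", "EXTRA_CYTOPLASMIC")
ENZYME_METRICS = tuple(e.value.lower() for e in EnzymeClass)
HEME_METRICS = ("multiheme_ec_om_cw", "multiheme_unk_sp", "pp_heme", "cm_heme")
ALL_METRICS = COMPARTMENT_METRICS + ENZYME_METRICS + HEME_METRICS

_CATEGORY_SHORT = {
    Location.EXTRACELLULAR: "EC",
    Location.OUTER_MEMBRANE: "OM",
    Location.CELL_WALL: "CW",
    Location.PERIPLASMIC: "PP",
    Location.CYTOPLASMIC_MEMBRANE: "CM",
    Location.CYTOPLASMIC: "CY",
    Location.UNKNOWN: "UNK",
}


@dataclass
class MagProfile:
    mag_id: str
    counts: dict
    abundant: bool
    mean_relative_abundance: float | None = None
    flags: set = field(default_factory=set)

    def as_row(self) -> dict:
        row = {"mag_id": self.mag_id, **self.counts,
               "mean_relative_abundance": self.mean_relative_abundance,
               "abundant": self.abundant,
               "flags": ",".join(sorted(f"{m}:HIGH" for m, _ in self.flags))}
        return row


def build_mag_profile(mag_id: str,
                      assignments: Sequence[CompartmentAssignment],
                      enzyme_calls: Sequence[EnzymeCall],
                      heme_profiles: Mapping[str, HemeProfile],
                      abundance: AbundanceRecord | None,
                      config: PipelineConfig | None = None) -> MagProfile:
    """Count vector for one MAG over compartments, enzyme and heme classes.

    *assignments* and *enzyme_calls* must already be restricted to this MAG;
    *heme_profiles* maps protein id → profile for every scanned protein.
    A missing abundance record yields ``abundant=False`` (with the value left
    unset) rather than an error.
    """
    config = config or PipelineConfig()
    counts = {m: 0 for m in ALL_METRICS}
    by_protein = {a.protein_id: a for a in assignments}
    if len(by_protein) != len(assignments):
        raise IntegrityError(f"MAG {mag_id!r}: duplicate compartment assignments")
    for a in assignments:
        counts[_CATEGORY_SHORT[a.category]] += 1
        if a.unk_sp:
            counts["UNK_SP"] += 1
        if a.is_extra_cytoplasmic:
            counts["EXTRA_CYTOPLASMIC"] += 1
    for call in enzyme_calls:
        counts[call.enzyme_class.value.lower()] += 1
    for pid, hp in heme_profiles.items():
        a = by_protein.get(pid)
        if a is None:
            continue
        cat = _CATEGORY_SHORT[a.category]
        if hp.is_multiheme and cat in ("EC", "OM", "CW"):
            counts["multiheme_ec_om_cw"] += 1
        if hp.is_multiheme and a.unk_sp:
            counts["multiheme_unk_sp"] += 1
        if hp.n_motifs >= 1 and cat == "PP":
            counts["pp_heme"] += 1
        if hp.n_motifs >= 1 and cat == "CM":
            counts["cm_heme"] += 1
    value = abundance.mean_relative_abundance if abundance is not None else None
    abundant = value is not None and value > config.abundance_cutoff
    return MagProfile(mag_id=mag_id, counts=counts, abundant=abundant,
                      mean_relative_abundance=value)


@dataclass(frozen=True)
class FlagResult:
    flagged: frozenset
    mean: float
    sd: float
    threshold: float


def flag_high_counts(values: Mapping[str, float],
                     config: PipelineConfig | None = None) -> FlagResult:
    """MAGs whose count exceeds mean + k·SD (sample SD, n−1; strict >)."""
    config = config or PipelineConfig()
    if len(values) < 2:
        raise UsageError("flagging needs counts from at least two MAGs")
    arr = np.asarray(list(values.values()), dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    threshold = mean + config.flag_sd_multiplier * sd
    flagged = frozenset(m for m, v in values.items() if v > threshold)
    return FlagResult(flagged=flagged, mean=mean, sd=sd, threshold=threshold)


def correlate_categories(profiles: pd.DataFrame,
                         x: str = "UNK_SP", y: str = "EXTRA_CYTOPLASMIC") -> tuple:
    """Pearson correlation (r, two-sided p) between two per-MAG metrics."""
    if len(profiles) < 3:
        raise UsageError("correlation needs at least three MAGs")
    xv = profiles[x].to_numpy(dtype=float)
    yv = profiles[y].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UsageError(f"correlation between {x} and {y} undefined: zero variance")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p)


@dataclass
class CohortSummary:
    """Cohort-level report: totals, signal-peptide percentages, flag
    statistics per metric, and the UNK+SP vs extra-cytoplasmic correlation."""

    totals: dict
    pct_with_sp: dict          # EC/OM/CW/PP: % with >=1 detector; UNK: % UNK+SP
    flag_stats: dict           # metric -> FlagResult
    pearson_r: float | None = None
    pearson_p: float | None = None


def summarize_cohort(catalog: pd.DataFrame, profiles: pd.DataFrame,
                     config: PipelineConfig | None = None) -> CohortSummary:
    """Build the cohort overview from the per-protein catalog and profiles."""
    config = config or PipelineConfig()
    totals = {m: int(profiles[m].sum()) if len(profiles) else 0 for m in ALL_METRICS}
    pct: dict[str, float | None] = {}
    for short, cat in (("EC", "EXTRACELLULAR"), ("OM", "OUTER_MEMBRANE"),
                       ("CW", "CELL_WALL"), ("PP", "PERIPLASMIC")):
        sub = catalog[catalog["category"] == cat] if len(catalog) else catalog
        pct[short] = (100.0 * (sub["sp_support"] >= 1).mean()) if len(sub) else None
    unk = catalog[catalog["category"] == "UNKNOWN"] if len(catalog) else catalog
    pct["UNK"] = (100.0 * unk["unk_sp"].mean()) if len(unk) else None
    flag_stats = {}
    if len(profiles) >= 2:
        for metric in ALL_METRICS:
            flag_stats[metric] = flag_high_counts(
                dict(zip(profiles["mag_id"], profiles[metric])), config
            )
    r = p = None
    if len(profiles) >= 3:
        try:
            r, p = correlate_categories(profiles)
        except UsageError:
            pass
    return CohortSummary(totals=totals, pct_with_sp=pct, flag_stats=flag_stats,
                         pearson_r=r, pearson_p=p)


# ---------------------------------------------------------------------------
# orthogroup matrix, ranking, clustering

def og_count_matrix(memberships: Iterable[OrthogroupMembership],
                    protein_to_mag: Mapping[str, str]) -> pd.DataFrame:
    """Orthogroup × MAG protein-count matrix from a membership table."""
    rows = []
    for m in memberships:
        mag = protein_to_mag.get(m.protein_id)
        if mag is None:
            raise IntegrityError(f"orthogroup row references unknown protein {m.protein_id!r}")
        rows.append((m.og_id, mag))
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["og_id", "mag_id"])
    mat = df.value_counts().unstack(fill_value=0)
    return mat.sort_index(axis=0).sort_index(axis=1)


def rank_ogs(matrix: pd.DataFrame, mag_subset: Sequence[str],
             config: PipelineConfig | None = None) -> list[str]:
    """Top-N orthogroups ranked by summed counts over a MAG subset.

    Ties are broken by orthogroup id ascending so the ranking is deterministic.
    """
    config = config or PipelineConfig()
    if not len(mag_subset):
        raise UsageError("rank_ogs needs a non-empty MAG subset")
    missing = set(mag_subset) - set(matrix.columns)
    if missing:
        raise UsageError(f"MAGs absent from the orthogroup matrix: {sorted(missing)}")
    sums = matrix[list(mag_subset)].sum(axis=1)
    order = sorted(sums.index, key=lambda og: (-sums[og], og))
    return order[: config.top_og_n]


@dataclass
class ClusteringResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list
    row_newick: str
    col_newick: str
    scaled: pd.DataFrame


def _correlation_condensed(x: np.ndarray, labels: Sequence[str], axis_name: str) -> np.ndarray:
    sds = x.std(axis=1)
    for label, sd in zip(labels, sds):
        if sd == 0:
            raise UsageError(f"constant {axis_name} {label!r}: correlation distance undefined")
    return pdist(x, metric="correlation")


def _linkage_to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Newick string with ultrametric branch lengths (leaf height = merge
    distance / 2, branch length = parent height − child height)."""
    tree = to_tree(z)

    def height(node) -> float:
        return node.dist / 2.0

    def render(node, parent_h: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_h:.10g}"
        h = height(node)
        left = render(node.left, h)
        right = render(node.right, h)
        return f"({left},{right}):{parent_h - h:.10g}"

    root_h = height(tree)
    body = f"({render(tree.left, root_h)},{render(tree.right, root_h)})"
    return body + ";"


def cluster_og_matrix(matrix: pd.DataFrame) -> ClusteringResult:
    """Cluster orthogroups (rows) and MAGs (columns) the heatmap way.

    Rows are centered and scaled to unit variance (sample SD); the pairwise
    distance is 1 − Pearson r and merging uses average linkage (UPGMA) with
    deterministic tie-breaking by lowest index pair. Dendrogram heights are
    correlation distances; Newick branch lengths halve them so leaf-to-leaf
    path lengths equal merge distances.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise UsageError("clustering needs at least a 2x2 matrix")
    x = matrix.to_numpy(dtype=float)
    row_sd = x.std(axis=1, ddof=1)
    for label, sd in zip(matrix.index, row_sd):
        if sd == 0:
            raise UsageError(f"constant row {label!r}: cannot scale to unit variance")
    scaled = (x - x.mean(axis=1, keepdims=True)) / row_sd[:, None]
    row_d = _correlation_condensed(scaled, list(matrix.index), "row")
    col_d = _correlation_condensed(scaled.T, list(matrix.columns), "column")
    row_z = linkage(row_d, method="average")
    col_z = linkage(col_d, method="average")
    row_tree, col_tree = to_tree(row_z), to_tree(col_z)
    return ClusteringResult(
        row_linkage=row_z,
        col_linkage=col_z,
        row_order=[matrix.index[i] for i in row_tree.pre_order()],
        col_order=[matrix.columns[i] for i in col_tree.pre_order()],
        row_newick=_linkage_to_newick(row_z, list(matrix.index)),
        col_newick=_linkage_to_newick(col_z, list(matrix.columns)),
        scaled=pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns),
    )
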