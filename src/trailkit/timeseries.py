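"""Two-stage clustering and enrichment of time-resolved expression data.

The workflow filters out genes with little expression change over time,
then clusters the rest in two stages: a strict first-stage clustering that
yields small, highly homogeneous clusters, and a second stage that merges
similar first-stage mean curves into "super-clusters".  Super-clusters are
ordered by their most active point in time (the peak of the z-scored mean
curve), and every cluster and super-cluster is tested for category
over-representation.

The default distance is the Euclidean distance between expression
gradients: row values are first differenced against the (possibly
irregular) time grid, so two genes with parallel but offset curves are at
distance zero.  The default linkage is complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .enrich import EnrichmentRecord, adjust_records, ora
from .geneset import GeneSetCollection, harmonize

logger = logging.getLogger(__name__)

DISTANCES = ("gradient_euclidean", "euclidean", "one_minus_pearson")
LINKAGES = ("complete", "average")

#: Minimum first-stage cluster size admitted to enrichment; smaller strict
#: clusters are discarded (their genes reported as unassigned).
DEFAULT_MIN_CLUSTER_SIZE = 5

#: Default range filter on (assumed log-scale) expression values.
DEFAULT_MIN_RANGE = 1.0


@dataclass
class ExpressionSeries:
    """Normalized expression values on a common, strictly increasing time grid."""

    genes: list[str]
    timepoints: np.ndarray  # shape (T,), hours
    values: np.ndarray  # shape (genes, T)

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate gene ids")
        if self.timepoints.ndim != 1 or self.timepoints.size < 3:
            raise ValueError("need >= 3 timepoints")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.values.shape != (len(self.genes), self.timepoints.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.genes)}, {self.timepoints.size})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")

    def subset(self, genes: Sequence[str]) -> "ExpressionSeries":
        index = {g: i for i, g in enumerate(self.genes)}
        rows = [index[g] for g in genes]
        return ExpressionSeries(list(genes), self.timepoints, self.values[rows])


def read_matrix(path: str | Path) -> ExpressionSeries:
    """Read a white-space separated matrix: first column gene ids, header of
    numeric time labels."""
    df = pd.read_csv(path, sep=r"\s+", index_col=0)
    try:
        timepoints = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"{path}: header must be numeric time labels") from exc
    return ExpressionSeries(list(df.index.astype(str)), timepoints, df.to_numpy(dtype=float))


def write_matrix(series: ExpressionSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        series.values, index=series.genes, columns=[f"{t:g}" for t in series.timepoints]
    )
    df.to_csv(path, sep="\t", index_label="gene_id")


def filter_low_change(series: ExpressionSeries, min_range: float = DEFAULT_MIN_RANGE) -> ExpressionSeries:
    """Remove genes whose max-min expression over time is below ``min_range``."""
    if min_range < 0:
        raise ValueError("min_range must be >= 0")
    ranges = series.values.max(axis=1) - series.values.min(axis=1)
    keep = ranges >= min_range
    if not keep.any():
        raise ValueError(
            f"min_range={min_range} removed all {len(series.genes)} genes; lower the threshold"
        )
    kept = [g for g, k in zip(series.genes, keep) if k]
    logger.info("range filter kept %d/%d genes", len(kept), len(series.genes))
    return ExpressionSeries(kept, series.timepoints, series.values[keep])


def gradients(values: np.ndarray, timepoints: np.ndarray) -> np.ndarray:
    """Per-interval slopes (v[i+1]-v[i]) / (t[i+1]-t[i]), rowwise."""
    timepoints = np.asarray(timepoints, dtype=float)
    dt = np.diff(timepoints)
    if np.any(dt == 0):
        raise ValueError("duplicate timepoints")
    return np.diff(np.atleast_2d(values), axis=1) / dt


def gradient_distance(x: np.ndarray, y: np.ndarray, timepoints: np.ndarray) -> float:
    """Euclidean distance between the gradient vectors of two series rows.

    Invariant to additive offsets: parallel curves are at distance 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("rows must have equal length >= 2")
    gx = gradients(x, timepoints)[0]
    gy = gradients(y, timepoints)[0]
    return float(np.linalg.norm(gx - gy))


def _distance_matrix(series: ExpressionSeries, distance: str) -> np.ndarray:
    if distance == "gradient_euclidean":
        return pdist(gradients(series.values, series.timepoints))
    if distance == "euclidean":
        return pdist(series.values)
    if distance == "one_minus_pearson":
        if series.values.shape[1] < 2:
            raise ValueError("pearson distance needs >= 2 timepoints")
        corr = np.corrcoef(series.values)
        d = 1.0 - corr
        np.fill_diagonal(d, 0.0)
        return squareform(np.maximum(d, 0.0), checks=False)
    raise ValueError(f"unknown distance {distance!r}; expected one of {DISTANCES}")


def _linkage(series: ExpressionSeries, distance: str, linkage: str) -> np.ndarray:
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    dmat = _distance_matrix(series, distance)
    if not np.all(np.isfinite(dmat)):
        raise ValueError("non-finite distances (constant rows with pearson distance?)")
    return hierarchy.linkage(dmat, method=linkage)


def linkage_heights(
    series: ExpressionSeries,
    distance: str = "gradient_euclidean",
    linkage: str = "complete",
) -> np.ndarray:
    """Sorted dendrogram merge heights -- a helper for choosing cut values.

    Cut heights are data-scale dependent, so they are required parameters
    of :func:`hier_cluster`/:func:`two_stage`; inspecting the gaps in this
    distribution is the intended way to pick them.
    """
    return np.sort(_linkage(series, distance, linkage)[:, 2])


def hier_cluster(
    series: ExpressionSeries,
    distance: str = "gradient_euclidean",
    linkage: str = "complete",
    cut: float = 1.0,
) -> dict[str, list[str]]:
    """Agglomerative clustering cut at height ``cut``.

    Genes are sorted lexicographically before clustering so that equal
    merge heights resolve deterministically.  Cluster ids are ``C1..Ck``,
    numbered by each cluster's lexicographically smallest member.
    """
    if cut <= 0:
        raise ValueError("cut must be > 0")
    if len(series.genes) < 2:
        raise ValueError("need >= 2 genes to cluster")
    order = sorted(range(len(series.genes)), key=lambda i: series.genes[i])
    sorted_series = ExpressionSeries(
        [series.genes[i] for i in order], series.timepoints, series.values[order]
    )
    Z = _linkage(sorted_series, distance, linkage)
    labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    by_label: dict[int, list[str]] = {}
    for gene, lab in zip(sorted_series.genes, labels):
        by_label.setdefault(int(lab), []).append(gene)
    groups = sorted(by_label.values(), key=lambda genes: genes[0])
    return {f"C{i+1}": genes for i, genes in enumerate(groups)}


@dataclass
class ClusterTree:
    """Two-level clustering: strict clusters nested in super-clusters."""

    clusters: dict[str, list[str]]
    super_clusters: dict[str, list[str]]  # sc-id -> cluster ids
    cluster_means: dict[str, np.ndarray]
    super_means: dict[str, np.ndarray]
    discarded: list[str]
    timepoints: np.ndarray
    order: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        """All post-filter genes: assigned plus discarded."""
        assigned = [g for genes in self.clusters.values() for g in genes]
        return assigned + list(self.discarded)

    def super_members(self, sc_id: str) -> list[str]:
        return sorted(g for cid in self.super_clusters[sc_id] for g in self.clusters[cid])

    def membership_frame(self) -> pd.DataFrame:
        cluster_of = {g: cid for cid, genes in self.clusters.items() for g in genes}
        super_of = {cid: sid for sid, cids in self.super_clusters.items() for cid in cids}
        rows = [
            {"gene_id": g, "cluster": cid, "super_cluster": super_of[cid]}
            for g, cid in sorted(cluster_of.items())
        ]
        rows += [
            {"gene_id": g, "cluster": "unassigned", "super_cluster": "unassigned"}
            for g in sorted(self.discarded)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "cluster", "super_cluster"])


def two_stage(
    series: ExpressionSeries,
    strict_cut: float,
    super_cut: float,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    distance: str = "gradient_euclidean",
    linkage: str = "complete",
) -> ClusterTree:
    """Strict clustering followed by super-clustering of cluster mean curves.

    Stage 1 cuts the gene dendrogram at ``strict_cut``; clusters smaller
    than ``min_cluster_size`` are discarded and their genes reported as
    unassigned.  Stage 2 clusters the surviving clusters' mean curves
    (arithmetic means of member rows) at ``super_cut`` with the same
    distance and linkage.
    """
    if not strict_cut < super_cut:
        raise ValueError(f"strict_cut ({strict_cut}) must be < super_cut ({super_cut})")
    stage1 = hier_cluster(series, distance, linkage, cut=strict_cut)

    discarded: list[str] = []
    clusters: dict[str, list[str]] = {}
    for cid, genes in stage1.items():
        if len(genes) >= min_cluster_size:
            clusters[genes[0]] = genes  # keyed temporarily by smallest member
        else:
            discarded.extend(genes)
    if len(clusters) < 2:
        raise ValueError(
            f"only {len(clusters)} cluster(s) of size >= {min_cluster_size} survived stage 1; "
            "relax strict_cut or min_cluster_size"
        )
    # renumber surviving clusters deterministically
    clusters = {f"C{i+1}": genes for i, genes in enumerate(sorted(clusters.values(), key=lambda g: g[0]))}

    index = {g: i for i, g in enumerate(series.genes)}
    cluster_means = {
        cid: series.values[[index[g] for g in genes]].mean(axis=0)
        for cid, genes in clusters.items()
    }

    mean_series = ExpressionSeries(
        list(cluster_means), series.timepoints, np.vstack(list(cluster_means.values()))
    )
    stage2 = hier_cluster(mean_series, distance, linkage, cut=super_cut)
    super_clusters = {
        f"SC{i+1}": cids for i, (_, cids) in enumerate(sorted(stage2.items(), key=lambda kv: kv[1][0]))
    }
    super_means = {
        sid: series.values[[index[g] for cid in cids for g in clusters[cid]]].mean(axis=0)
        for sid, cids in super_clusters.items()
    }
    tree = ClusterTree(
        clusters=clusters,
        super_clusters=super_clusters,
        cluster_means=cluster_means,
        super_means=super_means,
        discarded=sorted(discarded),
        timepoints=series.timepoints,
    )
    tree.order = order_superclusters(tree)
    if discarded:
        logger.info("discarded %d genes in clusters smaller than %d", len(discarded), min_cluster_size)
    return tree


def order_superclusters(tree: ClusterTree, timepoints: np.ndarray | None = None) -> list[str]:
    """Order super-clusters by their most active point in time.

    The peak time is the timepoint of the maximum of the z-scored
    super-cluster mean curve (z-scoring keeps amplitude differences from
    dominating).  Ties are broken by larger membership first, then by id.
    """
    t = tree.timepoints if timepoints is None else np.asarray(timepoints, dtype=float)

    def peak_time(sid: str) -> float:
        curve = tree.super_means[sid]
        sd = curve.std()
        z = (curve - curve.mean()) / sd if sd > 0 else np.zeros_like(curve)
        return float(t[int(np.argmax(z))])

    sizes = {sid: len(tree.super_members(sid)) for sid in tree.super_clusters}
    return sorted(tree.super_clusters, key=lambda sid: (peak_time(sid), -sizes[sid], sid))


def enrich_clusters(
    tree: ClusterTree,
    coll: GeneSetCollection,
    correction: str = "bh",
) -> dict[tuple[str, str], list[EnrichmentRecord]]:
    """ORA per cluster and per super-cluster against the post-filter universe.

    Keys are ``("cluster", id)`` and ``("super", id)``; p-values are
    corrected across categories within each key.  Discarded (unassigned)
    genes belong to the universe but are never used as a test set.
    """
    universe = frozenset(tree.genes)
    coll = harmonize(coll, universe)
    results: dict[tuple[str, str], list[EnrichmentRecord]] = {}

    def run(level: str, ident: str, members: Sequence[str]) -> None:
        records = [
            ora(members, coll.members(cid), universe, direction="over",
                category_id=cid, name=coll.display_name(cid))
            for cid in coll.categories
        ]
        records.sort(key=lambda r: (r.p_raw, r.category_id))
        results[(level, ident)] = adjust_records(records, method=correction)

    for cid, genes in tree.clusters.items():
        run("cluster", cid, genes)
    for sid in tree.super_clusters:
        run("super", sid, tree.super_members(sid))
    return results


def write_mean_curves(tree: ClusterTree, path: str | Path) -> None:
    cols = [f"{t:g}" for t in tree.timepoints]
    rows = []
    for cid, curve in tree.cluster_means.items():
        rows.append({"id": cid, "level": "cluster", **dict(zip(cols, curve))})
    for sid, curve in tree.super_means.items():
        rows.append({"id": sid, "level": "super", **dict(zip(cols, curve))})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
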