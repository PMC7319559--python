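"""Deterministic synthetic fixtures with known ground truth.

One generator per workflow: histone-mark peak tracks with planted per-gene
chromatin states, time-series matrices with planted two-level cluster
structure, and single-cell count matrices with planted group-specific
category activity.  Every generator writes exactly the text formats the
workflow readers consume, plus a ``truth.json`` describing the planted
structure, and is byte-deterministic for a fixed seed.

All randomness flows from one integer seed through named substreams
(derived by hashing the stream name), so adding an output file never
shifts the random numbers of another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .epigenome import GeneModel, write_gene_model
from .timeseries import ExpressionSeries, gradients, write_matrix

STATES = ("active", "poised", "repressed", "no_signal")

#: Marks planted per state, matching the default rule table: a bivalent
#: (poised) promoter carries H3K4me3 + H3K27me3, an active one H3K4me3 +
#: H3K27ac, a repressed gene H3K27me3 alone, and no_signal nothing.
STATE_MARKS: dict[str, list[tuple[str, str]]] = {
    "active": [("promoter", "H3K4me3"), ("promoter", "H3K27ac")],
    "poised": [("promoter", "H3K4me3"), ("promoter", "H3K27me3")],
    "repressed": [("promoter", "H3K27me3")],
    "no_signal": [],
}

#: Age-group composition of the default single-cell fixture: a mouse
#: microglia aging atlas with 8330 cells across three age groups.
MICROGLIA_GROUP_SIZES: dict[str, int] = {"3mo": 2219, "18mo": 1998, "24mo": 4113}


def substream(seed: int, name: str) -> np.random.Generator:
    """A named random substream derived from the master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Epigenome fixture


@dataclass
class EpigenomeFixture:
    gene_model_path: Path
    bed_paths: dict[tuple[str, str], Path]  # (group, mark) -> path
    truth: dict[str, dict[str, str]]  # group -> gene -> state
    truth_path: Path


def make_epigenome_fixture(
    out_dir: str | Path,
    n_genes: int = 200,
    groups: Sequence[str] = ("group1", "group2"),
    seed: int = 0,
    gene_length: int = 2000,
    spacing: int = 20000,
) -> EpigenomeFixture:
    """Gene model + per-(group, mark) BED tracks with planted states.

    Genes are laid head-to-tail on one chromosome, alternating strands,
    spaced far enough apart that regulatory windows never overlap.  For
    each gene and group a target state is sampled uniformly and the marks
    the default rule table requires for that state are placed as short
    peaks at the promoter (around the TSS), so state assignment recovers
    the planted state exactly.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes: list[GeneModel] = []
    for i in range(n_genes):
        start = 5000 + i * spacing
        strand = "+" if i % 2 == 0 else "-"
        tss, tes = (start, start + gene_length) if strand == "+" else (start + gene_length, start)
        genes.append(GeneModel(f"G{i:05d}", "chr1", strand, tss, tes))
    gene_model_path = out / "genes.tsv"
    write_gene_model(genes, gene_model_path)

    all_marks = sorted({m for placements in STATE_MARKS.values() for _, m in placements})
    truth: dict[str, dict[str, str]] = {}
    bed_paths: dict[tuple[str, str], Path] = {}
    for group in groups:
        rng = substream(seed, f"epigenome/states/{group}")
        states = rng.choice(STATES, size=n_genes)
        truth[group] = {g.gene_id: s for g, s in zip(genes, states)}
        intervals: dict[str, list[tuple[str, int, int]]] = {m: [] for m in all_marks}
        for gene, state in zip(genes, states):
            for region, mark in STATE_MARKS[state]:
                assert region == "promoter"
                peak = (gene.chrom, max(0, gene.tss - 50), gene.tss + 50)
                intervals[mark].append(peak)
        for mark in all_marks:
            path = out / f"{group}_{mark}.bed"
            with open(path, "w") as fh:
                for chrom, s, e in sorted(intervals[mark]):
                    fh.write(f"{chrom}\t{s}\t{e}\n")
            bed_paths[(group, mark)] = path

    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump({"workflow": "epigenome", "seed": seed, "states": truth}, fh, indent=1)
    return EpigenomeFixture(gene_model_path, bed_paths, truth, truth_path)


# ---------------------------------------------------------------------------
# Time-series fixture


@dataclass
class TimeseriesFixture:
    matrix_path: Path
    series: ExpressionSeries
    super_labels: dict[str, int]  # gene -> planted super-group
    cluster_labels: dict[str, int]  # gene -> planted sub-cluster (global index)
    suggested_strict_cut: float
    suggested_super_cut: float
    truth_path: Path


def _bump(t: np.ndarray, peak: float, width: float, amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((t - peak) / width) ** 2)


def make_timeseries_fixture(
    out_dir: str | Path,
    k_super: int = 3,
    subclusters_per_super: int = 2,
    genes_per_cluster: int = 30,
    timepoints: Sequence[float] | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    amplitude: float = 5.0,
    width: float = 1.5,
) -> TimeseriesFixture:
    """Expression matrix with planted super-group / sub-cluster structure.

    The time grid defaults to 0..24 h in 2 h steps (13 timepoints, the
    sampling of an activated T-cell time course).  Each super-group is a
    Gaussian bump peaking at a distinct time; sub-cluster variants scale
    its amplitude by ``1 + 0.25*j`` (an additive offset would be invisible
    to the gradient metric).  Gene rows add i.i.d. Gaussian noise; the
    default ``noise_sd`` is 10% of the template amplitude.

    Suggested dendrogram cuts are derived analytically from the planted
    geometry and the noise model, never from clustering output.  With
    per-value noise sd ``s`` and time step ``dt``, a gradient component
    has variance ``2 s^2 / dt^2``, so two same-cluster genes sit at a
    typical gradient distance ``d_w = (sqrt(2) s / dt) * sqrt(2 (T-1))``.
    The strict cut is ``1.8 d_w`` (a complete-linkage diameter allowance),
    floored at half the smallest within-super template-variant distance so
    the noiseless case still splits sub-clusters; the super cut is the
    midpoint between the strict cut and the smallest between-super
    template distance.
    """
    if k_super < 2:
        raise ValueError("k_super must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.arange(0.0, 25.0, 2.0) if timepoints is None else np.asarray(timepoints, dtype=float)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    span = t[-1] - t[0]
    peaks = t[0] + span * (np.arange(k_super) + 0.5) / k_super
    templates = np.vstack([_bump(t, p, width, amplitude) for p in peaks])

    # every planted curve variant: super-template s scaled by 1 + 0.25*j
    variants = np.vstack(
        [templates[s] * (1.0 + 0.25 * j) for s in range(k_super) for j in range(subclusters_per_super)]
    )
    var_grads = gradients(variants, t)
    var_super = np.repeat(np.arange(k_super), subclusters_per_super)
    inter, intra = [], []
    for i in range(len(var_grads)):
        for j in range(i + 1, len(var_grads)):
            d = float(np.linalg.norm(var_grads[i] - var_grads[j]))
            (intra if var_super[i] == var_super[j] else inter).append(d)
    min_inter = min(inter)

    dt = float(np.median(np.diff(t)))
    d_within = (np.sqrt(2.0) * noise_sd / dt) * np.sqrt(2.0 * (t.size - 1))
    floor = 0.5 * min(intra) if intra else 0.25 * min_inter
    strict_cut = max(1.8 * d_within, floor)
    super_cut = 0.5 * (strict_cut + min_inter)
    if not strict_cut < super_cut:
        raise ValueError(
            "noise level too high relative to template separation to derive cuts; "
            "lower noise_sd or sharpen the templates"
        )

    rng = substream(seed, "timeseries/noise")
    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    super_labels: dict[str, int] = {}
    cluster_labels: dict[str, int] = {}
    cluster_index = 0
    for s in range(k_super):
        for j in range(subclusters_per_super):
            curve = templates[s] * (1.0 + 0.25 * j)
            for g in range(genes_per_cluster):
                gid = f"G_s{s}_c{j}_{g:03d}"
                gene_ids.append(gid)
                rows.append(curve + rng.normal(0.0, noise_sd, size=t.size))
                super_labels[gid] = s
                cluster_labels[gid] = cluster_index
            cluster_index += 1

    series = ExpressionSeries(gene_ids, t, np.vstack(rows))
    matrix_path = out / "matrix.tsv"
    write_matrix(series, matrix_path)
    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "workflow": "timeseries",
                "seed": seed,
                "super_labels": super_labels,
                "cluster_labels": cluster_labels,
                "peaks": peaks.tolist(),
                "suggested_strict_cut": strict_cut,
                "suggested_super_cut": super_cut,
            },
            fh,
            indent=1,
        )
    return TimeseriesFixture(
        matrix_path, series, super_labels, cluster_labels, strict_cut, super_cut, truth_path
    )


# ---------------------------------------------------------------------------
# Single-cell fixture


@dataclass
class SingleCellFixture:
    matrix_path: Path
    genes_path: Path
    cells_path: Path
    annotation_path: Path
    gmt_path: Path
    truth: dict[str, str]  # group -> planted-active category
    truth_path: Path


def make_singlecell_fixture(
    out_dir: str | Path,
    groups_with_sizes: Mapping[str, int] | None = None,
    n_genes: int = 500,
    genes_per_category: int = 25,
    effect_fraction: float = 0.9,
    baseline_fraction: float = 0.1,
    background_rate: float = 0.1,
    seed: int = 0,
) -> SingleCellFixture:
    """Sparse count matrix with one planted-active category per cell group.

    Defaults reproduce the age-group composition of the microglia aging
    atlas (3mo: 2219, 18mo: 1998, 24mo: 4113 cells).  Each group gets one
    disjoint planted category; a cell expresses each gene of a category
    with probability ``effect_fraction`` when its group is planted-active
    for that category and ``baseline_fraction`` otherwise; background
    genes are expressed at ``background_rate``.  Expressed entries draw a
    count of 1 + Poisson(1).
    """
    if not 0 <= baseline_fraction < effect_fraction <= 1:
        raise ValueError("require 0 <= baseline_fraction < effect_fraction <= 1")
    sizes = dict(MICROGLIA_GROUP_SIZES) if groups_with_sizes is None else dict(groups_with_sizes)
    if genes_per_category * len(sizes) > n_genes:
        raise ValueError("not enough genes for disjoint planted categories")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = [f"g{i:05d}" for i in range(n_genes)]
    categories: dict[str, list[str]] = {}
    truth: dict[str, str] = {}
    for gi, group in enumerate(sizes):
        cid = f"pathway_{group}"
        categories[cid] = genes[gi * genes_per_category : (gi + 1) * genes_per_category]
        truth[group] = cid

    cat_of_gene: dict[str, str] = {g: cid for cid, gl in categories.items() for g in gl}
    expr_prob = np.empty((len(sizes), n_genes))
    for gi, group in enumerate(sizes):
        for gj, gene in enumerate(genes):
            cid = cat_of_gene.get(gene)
            if cid is None:
                expr_prob[gi, gj] = background_rate
            elif truth[group] == cid:
                expr_prob[gi, gj] = effect_fraction
            else:
                expr_prob[gi, gj] = baseline_fraction

    cells: list[str] = []
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    col = 0
    for gi, (group, size) in enumerate(sizes.items()):
        rng = substream(seed, f"singlecell/counts/{group}")
        for _ in range(size):
            cells.append(f"{group}_cell{len(cells):05d}")
            expressed = np.flatnonzero(rng.random(n_genes) < expr_prob[gi])
            counts = 1 + rng.poisson(1.0, size=expressed.size)
            rows.extend(expressed.tolist())
            cols.extend([col] * expressed.size)
            vals.extend(counts.tolist())
            col += 1

    matrix_path = out / "matrix.mtx"
    with open(matrix_path, "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{n_genes} {len(cells)} {len(vals)}\n")
        for r, c, v in zip(rows, cols, vals):
            fh.write(f"{r + 1} {c + 1} {v}\n")
    genes_path = out / "genes.txt"
    genes_path.write_text("".join(g + "\n" for g in genes))
    cells_path = out / "cells.txt"
    cells_path.write_text("".join(c + "\n" for c in cells))

    annotation_path = out / "annotation.tsv"
    with open(annotation_path, "w") as fh:
        fh.write("cell_id\tage_group\n")
        for c in cells:
            fh.write(f"{c}\t{c.rsplit('_cell', 1)[0]}\n")

    gmt_path = out / "categories.gmt"
    with open(gmt_path, "w") as fh:
        for cid, members in categories.items():
            fh.write("\t".join([cid, f"planted category for {cid.split('_', 1)[1]}", *members]) + "\n")

    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "workflow": "singlecell",
                "seed": seed,
                "group_sizes": sizes,
                "active_categories": truth,
                "effect_fraction": effect_fraction,
                "baseline_fraction": baseline_fraction,
                "background_rate": background_rate,
            },
            fh,
            indent=1,
        )
    return SingleCellFixture(
        matrix_path, genes_path, cells_path, annotation_path, gmt_path, truth, truth_path
    )
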