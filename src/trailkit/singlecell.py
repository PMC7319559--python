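"""Per-cell enrichment and chi-square characterization of cell groups.

Each cell's set of expressed genes is tested for category
over-representation against the global gene universe (the matrix genes),
giving a cells x categories matrix of adjusted p-values and boolean
"enriched" calls.  Cell groups defined by an annotation column (age group,
tissue, cluster label, ...) are then characterized per category with a
chi-square test on the 2x2 table of (in group / outside group) x
(enriched / not enriched), calling a category predominantly active or
inactive in the group.

Dimensionality reduction, graph clustering and pseudotime are consumed as
precomputed annotation columns; this module does not compute them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse, stats

from .enrich import adjust, chi_square_2x2
from .geneset import GeneSetCollection, harmonize

logger = logging.getLogger(__name__)

DEFAULT_SCALE = 1e4
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_GENES = 200
DEFAULT_MAX_COUNT_MADS = 3.0


@dataclass
class CellMatrix:
    """Genes x cells count matrix with optional normalized layer."""

    genes: list[str]
    cells: list[str]
    counts: sparse.csr_matrix  # genes x cells
    normalized: sparse.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell ids")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({len(self.genes)}, {len(self.cells)})"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def read_mtx(matrix_path: str | Path, genes_path: str | Path, cells_path: str | Path) -> CellMatrix:
    """Read a MatrixMarket coordinate triplet with row/column id files.

    Rows are genes, columns cells (1-based in the file, 0-based
    internally); duplicate (i, j) entries are summed.
    """
    genes = [line.strip() for line in open(genes_path) if line.strip()]
    cells = [line.strip() for line in open(cells_path) if line.strip()]
    mat = spio.mmread(matrix_path)
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix dimensions {mat.shape} do not match id files ({len(genes)}, {len(cells)})"
        )
    return CellMatrix(genes=genes, cells=cells, counts=sparse.csr_matrix(mat))


def write_mtx(m: CellMatrix, matrix_path: str | Path, genes_path: str | Path, cells_path: str | Path) -> None:
    spio.mmwrite(str(matrix_path), sparse.coo_matrix(m.counts))
    Path(genes_path).write_text("".join(g + "\n" for g in m.genes))
    Path(cells_path).write_text("".join(c + "\n" for c in m.cells))


def read_dense(path: str | Path) -> CellMatrix:
    """Read a dense white-space separated genes x cells matrix.

    First column gene ids, header row of cell ids.
    """
    df = pd.read_csv(path, sep=r"\s+", index_col=0)
    return CellMatrix(
        genes=list(df.index.astype(str)),
        cells=list(df.columns.astype(str)),
        counts=sparse.csr_matrix(df.to_numpy(dtype=float)),
    )


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Annotation TSV: ``cell_id`` column plus arbitrary label columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in df.columns:
        raise ValueError(f"{path}: annotation file needs a 'cell_id' column")
    if df["cell_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate cell ids in annotation")
    return df.set_index("cell_id")


# ---------------------------------------------------------------------------
# Filtering and normalization


def filter_cells(
    m: CellMatrix,
    min_genes: int = DEFAULT_MIN_GENES,
    max_count_mads: float = DEFAULT_MAX_COUNT_MADS,
) -> tuple[CellMatrix, list[str]]:
    """Drop low-complexity and high-count cells; returns (matrix, dropped ids).

    Cells with fewer than ``min_genes`` detected genes are treated as empty
    droplets/wells.  Cells whose total count exceeds
    ``median + max_count_mads * MAD`` of the per-cell totals are treated as
    doublet candidates; pass ``max_count_mads=inf`` to disable.
    """
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    csc = m.counts.tocsc()
    detected = (csc > 0).sum(axis=0).A1
    totals = csc.sum(axis=0).A1
    keep = detected >= min_genes
    if np.isfinite(max_count_mads):
        med = float(np.median(totals))
        mad = float(np.median(np.abs(totals - med)))
        keep &= totals <= med + max_count_mads * mad
    if not keep.any():
        raise ValueError("all cells removed by filtering; relax min_genes/max_count_mads")
    dropped = [c for c, k in zip(m.cells, keep) if not k]
    if dropped:
        logger.info("filtered out %d/%d cells", len(dropped), m.n_cells)
    kept_idx = np.flatnonzero(keep)
    filtered = CellMatrix(
        genes=list(m.genes),
        cells=[m.cells[i] for i in kept_idx],
        counts=csc[:, kept_idx].tocsr(),
    )
    return filtered, dropped


def normalize(m: CellMatrix, scale: float = DEFAULT_SCALE) -> CellMatrix:
    """Library-size normalization: ``log(1 + count * scale / cell_total)``.

    Stores the result in ``normalized``.  Every cell must have a positive
    total (filter first).
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    csc = m.counts.tocsc().astype(float)
    totals = csc.sum(axis=0).A1
    if np.any(totals == 0):
        zero = [m.cells[i] for i in np.flatnonzero(totals == 0)][:5]
        raise ValueError(f"cells with zero total counts (e.g. {zero}); filter before normalizing")
    norm = csc.copy()
    norm.data = norm.data * (scale / totals[np.repeat(np.arange(len(totals)), np.diff(csc.indptr))])
    norm.data = np.log1p(norm.data)
    return CellMatrix(
        genes=list(m.genes), cells=list(m.cells), counts=m.counts, normalized=norm.tocsr()
    )


def expressed_set(m: CellMatrix, cell: str, mode: str = "nonzero", k: int = 0) -> frozenset[str]:
    """The genes counted as "expressed" in one cell.

    ``nonzero``: genes with count > 0.  ``top_k``: the ``k`` genes with the
    highest normalized value (ties broken lexicographically; requires a
    normalized layer and k <= gene count).
    """
    try:
        j = m.cells.index(cell)
    except ValueError:
        raise KeyError(f"unknown cell {cell!r}") from None
    if mode == "nonzero":
        col = m.counts.getcol(j)
        return frozenset(m.genes[i] for i in col.nonzero()[0])
    if mode == "top_k":
        if k > m.n_genes:
            raise ValueError(f"k={k} exceeds gene count {m.n_genes}")
        layer = m.normalized if m.normalized is not None else m.counts
        vals = layer.getcol(j).toarray().ravel()
        order = sorted(range(m.n_genes), key=lambda i: (-vals[i], m.genes[i]))
        return frozenset(m.genes[i] for i in order[:k])
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Per-cell enrichment


@dataclass
class PerCellEnrichment:
    """Adjusted per-cell ORA p-values and boolean enriched calls."""

    cells: list[str]
    categories: list[str]
    p_adjusted: np.ndarray  # cells x categories
    enriched: np.ndarray  # boolean, cells x categories
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_adjusted, index=self.cells, columns=self.categories)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame().map(lambda v: f"{v:.6g}")
        df.to_csv(path, sep="\t", index_label="cell_id")


def percell_enrichment(
    m: CellMatrix,
    coll: GeneSetCollection,
    mode: str = "nonzero",
    k: int = 0,
    alpha: float = DEFAULT_ALPHA,
    correction: str = "bh",
) -> PerCellEnrichment:
    """ORA of every cell's expressed set against every category.

    The universe is the full set of matrix genes (a global background);
    the collection is harmonized to it.  Overlap counts are computed for
    all cells at once via a sparse category-indicator product, then
    converted to hypergeometric upper-tail p-values and corrected across
    categories within each cell.  A cell is called enriched for a category
    when its adjusted p-value is <= ``alpha``.
    """
    coll = harmonize(coll, frozenset(m.genes))
    categories = sorted(coll.categories)
    if not categories:
        return PerCellEnrichment(list(m.cells), [], np.zeros((m.n_cells, 0)),
                                 np.zeros((m.n_cells, 0), dtype=bool), alpha)

    gene_idx = {g: i for i, g in enumerate(m.genes)}
    indicator = sparse.lil_matrix((len(categories), m.n_genes), dtype=np.int64)
    for ci, cid in enumerate(categories):
        for g in coll.members(cid):
            indicator[ci, gene_idx[g]] = 1
    indicator = indicator.tocsr()

    if mode == "nonzero":
        expressed = (m.counts > 0).astype(np.int64).tocsc()
    elif mode == "top_k":
        cols = []
        for cell in m.cells:
            sel = expressed_set(m, cell, mode="top_k", k=k)
            col = np.zeros((m.n_genes, 1), dtype=np.int64)
            for g in sel:
                col[gene_idx[g], 0] = 1
            cols.append(sparse.csc_matrix(col))
        expressed = sparse.hstack(cols).tocsc()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n_per_cell = expressed.sum(axis=0).A1  # n
    if np.any(n_per_cell == 0):
        empty = [m.cells[i] for i in np.flatnonzero(n_per_cell == 0)][:5]
        raise ValueError(f"cells with empty expressed set (e.g. {empty}); filter first")
    K_per_cat = indicator.sum(axis=1).A1  # K
    overlaps = np.asarray((indicator @ expressed).todense())  # categories x cells
    N = m.n_genes

    # P(X >= k) for every (category, cell) pair
    p_raw = stats.hypergeom.sf(overlaps - 1, N, K_per_cat[:, None], n_per_cell[None, :])
    p_raw = np.clip(p_raw, np.finfo(float).tiny, 1.0).T  # cells x categories

    p_adj = np.vstack([adjust(row, method=correction) for row in p_raw])
    return PerCellEnrichment(
        cells=list(m.cells),
        categories=categories,
        p_adjusted=p_adj,
        enriched=p_adj <= alpha,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Group characterization


@dataclass
class GroupCharacterization:
    """Chi-square 2x2 result for one (group, category) pair."""

    group: tuple[str, str]  # (annotation name, value)
    category_id: str
    table: tuple[int, int, int, int]  # a, b, c, d
    chi2: float
    p_raw: float
    p_adjusted: float
    odds_ratio: float
    call: str  # predominantly_active | predominantly_inactive | ns


def characterize_groups(
    calls: PerCellEnrichment,
    annotation: pd.DataFrame,
    annotation_name: str,
    correction: str = "bh",
    alpha: float = DEFAULT_ALPHA,
) -> list[GroupCharacterization]:
    """Chi-square characterization of each annotation group per category.

    For every group value and category the 2x2 table is
    ``a`` = enriched cells in the group, ``b`` = non-enriched in the group,
    ``c`` = enriched outside, ``d`` = non-enriched outside.  Within each
    group, p-values are corrected across categories; a category is called
    ``predominantly_active`` when significant with odds ratio > 1 and
    ``predominantly_inactive`` when significant with odds ratio < 1.
    Degenerate tables (a zero margin) are recorded as ``ns`` with p = 1.
    """
    if annotation_name not in annotation.columns:
        raise ValueError(f"annotation column {annotation_name!r} not found")
    labels = annotation[annotation_name]
    missing = [c for c in calls.cells if c not in labels.index or pd.isna(labels.get(c))]
    if missing:
        raise ValueError(f"cells without {annotation_name!r} annotation (e.g. {missing[:5]})")
    cell_labels = np.array([labels[c] for c in calls.cells])

    results: list[GroupCharacterization] = []
    for value in sorted(set(cell_labels)):
        in_group = cell_labels == value
        if not in_group.any():
            raise ValueError(f"group {value!r} has no cells")
        group_rows: list[GroupCharacterization] = []
        for ci, cid in enumerate(calls.categories):
            enr = calls.enriched[:, ci]
            a = int(np.sum(enr & in_group))
            b = int(np.sum(~enr & in_group))
            c = int(np.sum(enr & ~in_group))
            d = int(np.sum(~enr & ~in_group))
            try:
                chi2, p, orat = chi_square_2x2(a, b, c, d)
            except ValueError:
                logger.warning(
                    "degenerate table for group %s=%s, category %s; recorded as ns",
                    annotation_name, value, cid,
                )
                chi2, p, orat = 0.0, 1.0, 1.0
            group_rows.append(
                GroupCharacterization(
                    group=(annotation_name, str(value)),
                    category_id=cid,
                    table=(a, b, c, d),
                    chi2=chi2,
                    p_raw=p,
                    p_adjusted=p,
                    odds_ratio=orat,
                    call="ns",
                )
            )
        adjusted = adjust([r.p_raw for r in group_rows], method=correction)
        for row, padj in zip(group_rows, adjusted):
            row.p_adjusted = padj
            if padj <= alpha and row.odds_ratio > 1:
                row.call = "predominantly_active"
            elif padj <= alpha and row.odds_ratio < 1:
                row.call = "predominantly_inactive"
        group_rows.sort(key=lambda r: (r.p_adjusted, -r.chi2, r.category_id))
        results.extend(group_rows)
    return results


def characterizations_to_frame(results: Sequence[GroupCharacterization]) -> pd.DataFrame:
    rows = [
        {
            "annotation": r.group[0],
            "group": r.group[1],
            "category_id": r.category_id,
            "a": r.table[0],
            "b": r.table[1],
            "c": r.table[2],
            "d": r.table[3],
            "chi2": r.chi2,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "odds_ratio": r.odds_ratio,
            "call": r.call,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def write_characterizations(results: Sequence[GroupCharacterization], path: str | Path) -> None:
    df = characterizations_to_frame(results)
    for col in ("chi2", "p_raw", "p_adjusted", "odds_ratio"):
        df[col] = df[col].map(lambda v: f"{v:.6g}")
    df.to_csv(path, sep="\t", index=False)


def write_summary_json(results: Sequence[GroupCharacterization], path: str | Path) -> None:
    """Per-group summary of significant categories, mirroring an
    enrichment-results table keyed by group."""
    summary: dict[str, list[dict]] = {}
    for r in results:
        if r.call != "ns":
            summary.setdefault(r.group[1], []).append(
                {
                    "category_id": r.category_id,
                    "chi2": r.chi2,
                    "p_adjusted": r.p_adjusted,
                    "odds_ratio": r.odds_ratio,
                    "call": r.call,
                }
            )
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1)


def plot_percell_pvalues(
    calls: PerCellEnrichment,
    coords: np.ndarray,
    category_id: str,
    path: str | Path,
) -> None:
    """Smoke-test scatter of cells colored by one category's -log10 p.

    ``coords`` is a cells x 2 array of precomputed 2D coordinates (e.g. a
    UMAP produced elsewhere).  Static output only.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ci = calls.categories.index(category_id)
    vals = -np.log10(np.clip(calls.p_adjusted[:, ci], 1e-300, 1.0))
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=vals, s=4, cmap="viridis")
    fig.colorbar(sc, label=f"-log10 adj. p ({category_id})")
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
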