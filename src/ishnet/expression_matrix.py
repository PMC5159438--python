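"""Gene × region expression matrices: assembly, clustering, heatmap export.

Collects scored :class:`~ishnet.ish_scoring.RegionExpression` records into a
matrix of expression factors, hierarchically clusters genes and regions
(average linkage; Euclidean or 1 − Pearson distance), and exports
heatmap-ready artifacts: the reordered matrix as TSV, dendrograms as
Newick strings with branch lengths, and a rendered image.

Clustering is deterministic: axis items are sorted lexicographically
before linkage so ties resolve by label order regardless of input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .ish_scoring import RegionExpression

__all__ = [
    "ExpressionMatrix",
    "Dendrogram",
    "build_matrix",
    "cluster_axis",
    "export_heatmap",
    "dendrogram_to_newick",
    "read_matrix",
]


@dataclass
class ExpressionMatrix:
    """Genes × regions grid of expression values.

    ``values`` is a DataFrame with gene rows and region columns.  When
    sourced from ISH scoring the entries are expression factors in
    [0, 28]; matrices read from microarray-style files are unrestricted.
    ``missing`` flags cells that were absent from the input records and
    were set to the fill value.
    """

    values: pd.DataFrame
    missing: pd.DataFrame | None = None
    categories: pd.DataFrame | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class Dendrogram:
    """Agglomerative clustering result for one matrix axis.

    ``merges`` is a SciPy-style linkage matrix over the (sorted) labels;
    ``labels`` gives the leaf names in pre-clustering order and
    ``leaf_order`` the left-to-right display order.
    """

    merges: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.merges)
        return [self.labels[i] for i in order]


def build_matrix(
    records: Iterable[RegionExpression], fill: float = 0.0
) -> ExpressionMatrix:
    """Assemble scored records into a genes × regions expression matrix.

    Duplicate entries for the same (gene, region) — typically the 2-3
    sectioning planes — are averaged.  Cells with no record are set to
    ``fill`` and flagged in ``missing``.  Conflicting categories between
    duplicates raise a warning, not an error.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to assemble")
    rows = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "region": [r.region for r in records],
            "E": [r.E for r in records],
            "category": [r.category for r in records],
        }
    )
    conflicts = rows.groupby(["gene", "region"])["category"].nunique()
    for (gene, region), n in conflicts.items():
        if n > 1:
            warnings.warn(
                f"conflicting categories for gene {gene!r} in region {region!r}; averaging E",
                stacklevel=2,
            )
    mean_e = rows.groupby(["gene", "region"])["E"].mean().unstack("region")
    mean_e = mean_e.sort_index(axis=0).sort_index(axis=1)
    missing = mean_e.isna()
    cats = (
        rows.groupby(["gene", "region"])["category"]
        .agg(lambda c: c.mode().iloc[0])
        .unstack("region")
        .reindex(index=mean_e.index, columns=mean_e.columns)
    )
    return ExpressionMatrix(values=mean_e.fillna(fill), missing=missing, categories=cats)


def _distance(
    data: np.ndarray, metric: Literal["euclidean", "correlation"], labels: Sequence[str]
) -> np.ndarray:
    if metric == "euclidean":
        return pdist(data, metric="euclidean")
    # 1 - Pearson correlation distance; undefined for constant rows
    sd = data.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(
            f"correlation distance undefined for constant rows: {', '.join(bad)}"
        )
    return pdist(data, metric="correlation")


def cluster_axis(
    matrix: ExpressionMatrix,
    axis: Literal["genes", "regions"] = "genes",
    metric: Literal["euclidean", "correlation"] = "euclidean",
    *,
    zscore_genes: bool = False,
) -> Dendrogram:
    """Average-linkage hierarchical clustering of one matrix axis.

    ``metric`` is Euclidean distance or one-minus-Pearson-correlation.
    ``zscore_genes`` standardizes each gene row before distances are
    computed (an alternative to clustering raw expression factors).
    Items are pre-sorted by label so tie-breaking is deterministic.
    """
    if axis not in ("genes", "regions"):
        raise ValueError("axis must be 'genes' or 'regions'")
    df = matrix.values
    if zscore_genes:
        sd = df.std(axis=1, ddof=0)
        if np.any(sd == 0):
            bad = list(df.index[sd == 0])
            raise ValueError(f"cannot z-score constant gene rows: {', '.join(bad)}")
        df = df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)
    obs = df if axis == "genes" else df.T
    obs = obs.sort_index()
    labels = list(obs.index.astype(str))
    if len(labels) < 2:
        raise ValueError(f"need at least 2 items on axis {axis!r} to cluster")
    dist = _distance(obs.to_numpy(dtype=float), metric, labels)
    merges = hierarchy.linkage(dist, method="average")
    return Dendrogram(merges=merges, labels=labels)


def dendrogram_to_newick(dendro: Dendrogram) -> str:
    """Render a dendrogram as a Newick string with branch lengths.

    Branch lengths are the height differences between a node and its
    parent merge, so leaf-to-root distances reproduce merge heights.
    """
    tree = hierarchy.to_tree(dendro.merges)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{dendro.labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def export_heatmap(
    matrix: ExpressionMatrix,
    row_dendro: Dendrogram,
    col_dendro: Dendrogram,
    path: str | Path,
    *,
    image_format: str = "png",
) -> dict[str, Path]:
    """Write the clustered heatmap artifact set to ``path`` (a prefix).

    Produces ``<path>.tsv`` (matrix reordered to the dendrogram leaf
    orders), ``<path>.rows.nwk`` / ``<path>.cols.nwk`` (dendrograms), and
    ``<path>.<fmt>`` (rendered heatmap).  Re-export from identical inputs
    is byte-identical.
    """
    path = Path(path)
    if str(path) == "":
        raise ValueError("empty output path")
    row_order = row_dendro.leaf_order
    col_order = col_dendro.leaf_order
    if sorted(row_order) != sorted(matrix.genes):
        raise ValueError("row dendrogram labels do not match matrix genes")
    if sorted(col_order) != sorted(matrix.regions):
        raise ValueError("column dendrogram labels do not match matrix regions")
    ordered = matrix.values.loc[row_order, col_order]

    path.parent.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    out["matrix"] = path.with_suffix(".tsv")
    ordered.to_csv(out["matrix"], sep="\t", float_format="%.6g")
    out["rows"] = path.with_suffix(".rows.nwk")
    out["rows"].write_text(dendrogram_to_newick(row_dendro) + "\n")
    out["cols"] = path.with_suffix(".cols.nwk")
    out["cols"].write_text(dendrogram_to_newick(col_dendro) + "\n")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.3 * len(col_order) + 2), max(3.0, 0.25 * len(row_order) + 2))
    )
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(col_order)), col_order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(row_order)), row_order, fontsize=6)
    fig.colorbar(im, ax=ax, label="expression")
    fig.tight_layout()
    out["image"] = path.with_suffix(f".{image_format}")
    fig.savefig(out["image"], dpi=120, metadata={"Software": None})
    plt.close(fig)
    return out


def read_matrix(path: str | Path, sep: str | None = None) -> ExpressionMatrix:
    """Read a plain genes × regions matrix from CSV/TSV with header row/column."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df)
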