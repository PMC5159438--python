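"""Weighted gene co-expression network analysis of gene × sample matrices.

The full chain, written from scratch on top of numpy/scipy/networkx:

1. Pearson correlation across samples (brain regions/structures).
2. Soft-threshold adjacency ``a_ij = |cor_ij|^beta`` (or the signed variant
   ``((1+cor)/2)^beta``), which downweights weak correlations without a
   hard cutoff.  ``beta`` defaults to 6, the conventional unsigned choice;
   a scale-free-fit scan is available for choosing it from data.
3. Topological overlap (TOM): pairwise similarity crediting both the
   direct connection and shared neighbours,
   ``tom_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
   ``l_ij = Σ_{u≠i,j} a_iu a_uj`` and connectivity ``k_i = Σ_{u≠i} a_iu``.
4. Module detection: average-linkage clustering of ``1 - TOM``, a static
   cut at a rescaled height, a minimum module size, and merging of modules
   whose eigengenes are highly correlated.
5. Module summaries: eigengene (first principal component of the
   standardized module submatrix), module membership kME with p-values,
   intramodular connectivity and hub genes, betweenness for module
   network plots.
6. Module preservation between two datasets: permutation Z-scores for a
   density and a connectivity statistic, averaged into Z_summary
   (conventionally: < 2 no evidence, 2-10 weak, > 10 strong preservation).

All stochastic steps take an explicit seed and reproduce bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "SampleMatrix",
    "ModulePartition",
    "Eigengene",
    "KMERecord",
    "PreservationReport",
    "correlation_matrix",
    "adjacency",
    "tom",
    "scale_free_fit",
    "pick_soft_threshold",
    "detect_modules",
    "module_eigengene",
    "kme",
    "intramodular_connectivity",
    "hub_genes",
    "betweenness",
    "zsummary",
    "read_sample_matrix",
    "UNASSIGNED",
]

#: Module id used for genes not belonging to any named module.
UNASSIGNED = 0

DEFAULT_BETA = 6.0
DEFAULT_CUT_HEIGHT = 0.25
DEFAULT_MIN_SIZE = 16
DEFAULT_MERGE_KME = 0.8


@dataclass
class SampleMatrix:
    """Genes × samples expression matrix for network construction."""

    values: pd.DataFrame
    standardized: bool = False

    @property
    def genes(self) -> list[str]:
        return list(self.values.index.astype(str))

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns.astype(str))

    def standardize(self) -> "SampleMatrix":
        """Z-score every gene across samples (ddof=0)."""
        df = self.values
        sd = df.std(axis=1, ddof=0)
        if np.any(sd == 0):
            bad = list(df.index[sd == 0].astype(str))
            raise ValueError(f"zero-variance genes cannot be standardized: {', '.join(bad)}")
        z = df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)
        return SampleMatrix(values=z, standardized=True)


@dataclass
class ModulePartition:
    """Gene → module assignment plus the cut parameters that produced it.

    Module ids are positive integers assigned by decreasing module size;
    0 means unassigned.
    """

    labels: pd.Series  # index: gene names, values: module ids
    cut_height: float
    min_size: int
    merge_kme: float

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module].astype(str))

    @property
    def module_ids(self) -> list[int]:
        ids = sorted(set(self.labels) - {UNASSIGNED})
        return ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.labels.index, "module": self.labels.values})


@dataclass
class Eigengene:
    """First principal component summarizing one module's expression."""

    module: int
    values: pd.Series  # per-sample, unit Euclidean norm
    variance_explained: float


@dataclass
class KMERecord:
    gene: str
    module: int
    kme: float
    p_value: float


@dataclass
class PreservationReport:
    """Permutation preservation of one reference module in a test network."""

    module: int
    size: int
    z_density: float
    z_connectivity: float
    z_summary: float
    observed_density: float
    observed_connectivity: float
    null_density_mean: float
    null_density_sd: float
    null_connectivity_mean: float
    null_connectivity_sd: float
    n_permutations: int
    seed: int


# --------------------------------------------------------------------------
# network construction
# --------------------------------------------------------------------------

def correlation_matrix(X: SampleMatrix) -> pd.DataFrame:
    """Pearson correlation between all gene pairs across samples."""
    df = X.values
    if df.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    sd = df.std(axis=1, ddof=0)
    if np.any(sd == 0):
        bad = list(df.index[sd == 0].astype(str))
        raise ValueError(f"zero-variance genes: {', '.join(bad)}")
    cor = np.corrcoef(df.to_numpy(dtype=float))
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=df.index, columns=df.index)


def adjacency(cor: pd.DataFrame, beta: float = DEFAULT_BETA, signed: bool = False) -> pd.DataFrame:
    """Soft-threshold connection-strength matrix from correlations.

    Unsigned: ``|cor|^beta``; signed: ``((1 + cor) / 2)^beta``.  The
    diagonal is fixed to 0 so connectivity sums exclude self-connections.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    c = cor.to_numpy(dtype=float)
    if np.max(np.abs(c)) > 1 + 1e-9:
        raise ValueError("correlations must lie in [-1, 1]")
    a = ((1.0 + c) / 2.0) ** beta if signed else np.abs(c) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    ``tom_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` where
    ``l_ij = Σ_{u≠i,j} a_iu a_uj`` counts shared-neighbour weight and
    ``k_i`` is node connectivity; the diagonal is set to 1.  With the
    diagonal of ``a`` zeroed, the matrix product ``A @ A`` yields ``l``
    directly.  Denominators below 1e-12 (isolated node pairs) are guarded.
    """
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    denom = np.where(denom < 1e-12, 1e-12, denom)
    t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def scale_free_fit(adj: pd.DataFrame, n_bins: int = 10) -> float:
    """R² of the log-log linear fit of the connectivity distribution.

    Bins node connectivities, regresses log10(frequency) on
    log10(mean connectivity) and returns the squared correlation — a
    diagnostic of scale-free topology, reported but never enforced.
    """
    k = adj.to_numpy(dtype=float).sum(axis=1)
    k = k[k > 0]
    if k.size < 2:
        return float("nan")
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = np.array(
        [k[(k >= lo) & (k < hi)].mean() if c > 0 else np.nan
         for lo, hi, c in zip(edges[:-1], edges[1:], counts)]
    )
    keep = (counts > 0) & np.isfinite(centers) & (centers > 0)
    if keep.sum() < 3:
        return float("nan")
    x = np.log10(centers[keep])
    y = np.log10(counts[keep] / counts.sum())
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pick_soft_threshold(
    cor: pd.DataFrame, betas: Sequence[float] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12), signed: bool = False
) -> pd.DataFrame:
    """Scan candidate powers and report the scale-free fit R² and mean k."""
    rows = []
    for b in betas:
        a = adjacency(cor, beta=b, signed=signed)
        rows.append(
            {
                "beta": b,
                "r_squared": scale_free_fit(a),
                "mean_connectivity": float(a.to_numpy().sum(axis=1).mean()),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# module detection
# --------------------------------------------------------------------------

def _cut_static(merges: np.ndarray, cut_height: float) -> np.ndarray:
    """Static cut of a dendrogram, ``cut_height`` below the root.

    Merge heights are min-max rescaled to [0, 1] and the tree is cut at
    rescaled height ``1 - cut_height``: merges within ``cut_height`` of
    the root separate modules, everything fusing lower stays together.
    Anchoring the cut to the root makes the same ``cut_height`` usable
    across datasets whose raw 1 - TOM heights occupy different ranges.
    """
    heights = merges[:, 2]
    h_lo, h_hi = heights.min(), heights.max()
    if h_hi <= h_lo:
        threshold = h_hi
    else:
        threshold = h_hi - cut_height * (h_hi - h_lo)
    return hierarchy.fcluster(merges, t=threshold, criterion="distance")


def detect_modules(
    tom_matrix: pd.DataFrame,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    min_size: int = DEFAULT_MIN_SIZE,
    merge_kme: float = DEFAULT_MERGE_KME,
    X: SampleMatrix | None = None,
) -> ModulePartition:
    """Cut the TOM dendrogram into co-expression modules.

    Genes are clustered by average linkage on the dissimilarity
    ``1 - TOM`` and the tree is cut statically at ``cut_height`` on the
    min-max rescaled merge heights (0 = first merge, 1 = root), so the cut
    level is comparable across datasets.  Clusters smaller than
    ``min_size`` become unassigned (module 0).  When expression data
    ``X`` is supplied, modules whose eigengenes correlate above
    ``merge_kme`` are merged iteratively.  Final ids are assigned by
    decreasing module size (ties by smallest member gene name).
    """
    if not 0 < cut_height < 1:
        raise ValueError("cut_height must be in (0, 1)")
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    genes = list(tom_matrix.index.astype(str))
    diss = 1.0 - tom_matrix.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    merges = hierarchy.linkage(squareform(diss, checks=False), method="average")
    raw = _cut_static(merges, cut_height)

    labels = pd.Series(raw, index=tom_matrix.index)
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_size]
    labels[labels.isin(small)] = UNASSIGNED

    if X is not None:
        labels = _merge_by_eigengene(labels, X, merge_kme)

    labels = _relabel_by_size(labels)
    if (labels == UNASSIGNED).all():
        warnings.warn("all genes unassigned at this cut", stacklevel=2)
    return ModulePartition(
        labels=labels, cut_height=cut_height, min_size=min_size, merge_kme=merge_kme
    )


def _merge_by_eigengene(labels: pd.Series, X: SampleMatrix, merge_kme: float) -> pd.Series:
    """Iteratively merge the most-correlated eigengene pair above threshold."""
    labels = labels.copy()
    while True:
        ids = sorted(set(labels) - {UNASSIGNED})
        if len(ids) < 2:
            return labels
        egs = {
            m: module_eigengene(X, list(labels.index[labels == m].astype(str))).values
            for m in ids
        }
        best, best_cor = None, merge_kme
        for i, m1 in enumerate(ids):
            for m2 in ids[i + 1 :]:
                c = abs(float(np.corrcoef(egs[m1], egs[m2])[0, 1]))
                if c > best_cor:
                    best, best_cor = (m1, m2), c
        if best is None:
            return labels
        labels[labels == best[1]] = best[0]


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != UNASSIGNED].value_counts()
    order = sorted(
        sizes.index,
        key=lambda m: (-sizes[m], min(str(g) for g in labels.index[labels == m])),
    )
    mapping = {old: new for new, old in enumerate(order, start=1)}
    mapping[UNASSIGNED] = UNASSIGNED
    return labels.map(mapping)


# --------------------------------------------------------------------------
# module summaries
# --------------------------------------------------------------------------

def module_eigengene(X: SampleMatrix, members: Sequence[str], module: int = 0) -> Eigengene:
    """First principal component across samples of a module's expression.

    Member genes are z-scored before the decomposition; the eigengene is
    the first right singular vector of the standardized genes × samples
    submatrix, unit-norm, with its sign oriented so the mean correlation
    with member genes is non-negative.  ``variance_explained`` is the
    first squared singular value over the total.
    """
    members = list(members)
    if not members:
        raise ValueError("module has no members")
    missing = [g for g in members if g not in X.values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {', '.join(missing)}")
    sub = SampleMatrix(values=X.values.loc[members]).standardize().values.to_numpy()
    _, s, vt = np.linalg.svd(sub, full_matrices=False)
    eig = vt[0]
    cors = np.array([np.corrcoef(row, eig)[0, 1] for row in sub])
    if cors.mean() < 0:
        eig = -eig
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return Eigengene(
        module=module,
        values=pd.Series(eig, index=X.values.columns),
        variance_explained=var_explained,
    )


def _cor_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the t-transform."""
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return float(np.finfo(float).tiny)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(max(p, np.finfo(float).tiny))


def kme(X: SampleMatrix, eigengenes: Sequence[Eigengene]) -> list[KMERecord]:
    """Module membership: |cor(gene, eigengene)| with t-transform p-values.

    Genes with zero variance get NaN kME and p and are flagged by the
    caller.  P-values are raw (no multiplicity adjustment); apply
    Benjamini-Hochberg downstream if desired.
    """
    n = X.values.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    out: list[KMERecord] = []
    vals = X.values.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    for eg in eigengenes:
        e = eg.values.to_numpy(dtype=float)
        for i, gene in enumerate(X.genes):
            if sd[i] == 0:
                out.append(KMERecord(gene=gene, module=eg.module, kme=float("nan"), p_value=float("nan")))
                continue
            r = float(np.corrcoef(vals[i], e)[0, 1])
            out.append(
                KMERecord(gene=gene, module=eg.module, kme=abs(r), p_value=_cor_pvalue(r, n))
            )
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment (optional, for kME p-values)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(list(pvalues), method="fdr_bh")[1]


def intramodular_connectivity(
    adj: pd.DataFrame, partition: ModulePartition
) -> pd.DataFrame:
    """kIM per gene: summed adjacency to same-module genes.

    Returns a frame with columns gene, module, kim; unassigned genes get
    kIM 0.  Hub genes are the top-kIM members of each module.
    """
    missing = [g for g in partition.labels.index if g not in adj.index]
    if missing:
        raise KeyError(f"partition genes absent from adjacency: {', '.join(map(str, missing))}")
    rows = []
    a = adj.to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(adj.index.astype(str))}
    for gene, module in partition.labels.items():
        gene = str(gene)
        if module == UNASSIGNED:
            kim = 0.0
        else:
            others = [idx[str(g)] for g in partition.members(module) if str(g) != gene]
            kim = float(a[idx[gene], others].sum()) if others else 0.0
        rows.append({"gene": gene, "module": module, "kim": kim})
    return pd.DataFrame(rows)


def hub_genes(kim: pd.DataFrame, top_k: int = 5) -> pd.DataFrame:
    """Top-k genes per module by intramodular connectivity, ties by name."""
    assigned = kim[kim["module"] != UNASSIGNED]
    return (
        assigned.sort_values(["module", "kim", "gene"], ascending=[True, False, True])
        .groupby("module", group_keys=False)
        .head(top_k)
        .reset_index(drop=True)
    )


def betweenness(
    weights: pd.DataFrame,
    module: Sequence[str],
    edge_threshold: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shortest-path node and edge betweenness of a module's network.

    Builds the graph on ``module`` genes with edges where the weight
    (adjacency or TOM) exceeds ``edge_threshold``; edge length is
    ``1 - weight`` (floored at 1e-9 so identical-weight ties resolve to
    the direct edge).  Betweenness is the standard accumulation over all
    source-target pairs, unnormalized; disconnected graphs are fine
    (paths only accumulate within components).
    """
    import networkx as nx

    module = [str(g) for g in module]
    g = nx.Graph()
    g.add_nodes_from(module)
    w = weights
    for i, u in enumerate(module):
        for v in module[i + 1 :]:
            wt = float(w.loc[u, v])
            if wt > edge_threshold:
                g.add_edge(u, v, weight=wt, length=max(1.0 - wt, 1e-9))
    if g.number_of_edges() == 0:
        raise ValueError("thresholded module graph has no edges")
    nb = nx.betweenness_centrality(g, weight="length", normalized=False)
    eb = nx.edge_betweenness_centrality(g, weight="length", normalized=False)
    nodes = pd.DataFrame(
        {"gene": list(nb.keys()), "betweenness": list(nb.values())}
    ).sort_values("gene").reset_index(drop=True)
    edges = pd.DataFrame(
        [
            {"gene_a": min(u, v), "gene_b": max(u, v),
             "weight": g[u][v]["weight"], "edge_betweenness": b}
            for (u, v), b in eb.items()
        ]
    ).sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    return nodes, edges


# --------------------------------------------------------------------------
# module preservation
# --------------------------------------------------------------------------

def _module_stats(
    a_ref: np.ndarray, a_test: np.ndarray, idx: np.ndarray
) -> tuple[float, float]:
    """Density and connectivity preservation statistics for one gene set.

    Density: mean off-diagonal adjacency among the set in the test
    network.  Connectivity: Pearson correlation between the reference and
    test within-set connectivity vectors.
    """
    sub_t = a_test[np.ix_(idx, idx)]
    m = idx.size
    density = float(sub_t.sum() / (m * (m - 1)))
    sub_r = a_ref[np.ix_(idx, idx)]
    k_r = sub_r.sum(axis=1)
    k_t = sub_t.sum(axis=1)
    if k_r.std() == 0 or k_t.std() == 0:
        connectivity = 0.0
    else:
        connectivity = float(np.corrcoef(k_r, k_t)[0, 1])
    return density, connectivity


def zsummary(
    X_ref: SampleMatrix,
    X_test: SampleMatrix,
    partition_ref: ModulePartition,
    beta: float = DEFAULT_BETA,
    n_perm: int = 200,
    seed: int = 0,
    signed: bool = False,
) -> list[PreservationReport]:
    """Permutation test of module preservation between two networks.

    For every reference module (≥ 3 genes after intersecting gene names
    between the datasets) the observed density and connectivity statistics
    are compared against a null of ``n_perm`` equally sized random gene
    sets drawn from the test network; each statistic is standardized to a
    Z-score and ``Z_summary`` is their mean.  Conventional reading:
    Z_summary < 2 no preservation, 2-10 weak, > 10 strong.
    """
    if n_perm < 50:
        raise ValueError("need at least 50 permutations")
    shared = [g for g in X_ref.genes if g in set(X_test.genes)]
    dropped = len(set(X_ref.genes) | set(X_test.genes)) - len(shared)
    if dropped:
        warnings.warn(f"{dropped} genes not shared between datasets were dropped", stacklevel=2)
    if len(shared) < 4:
        raise ValueError("too few shared genes between datasets")
    ref = SampleMatrix(values=X_ref.values.loc[shared])
    test = SampleMatrix(values=X_test.values.loc[shared])
    a_ref = adjacency(correlation_matrix(ref), beta=beta, signed=signed).to_numpy()
    a_test = adjacency(correlation_matrix(test), beta=beta, signed=signed).to_numpy()
    pos = {g: i for i, g in enumerate(shared)}
    rng = np.random.default_rng(seed)
    n_genes = len(shared)

    reports: list[PreservationReport] = []
    for module in partition_ref.module_ids:
        members = [g for g in partition_ref.members(module) if g in pos]
        m = len(members)
        if m < 3:
            warnings.warn(f"module {module} has < 3 shared genes; skipped", stacklevel=2)
            continue
        idx = np.array([pos[g] for g in members])
        obs_d, obs_c = _module_stats(a_ref, a_test, idx)
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        for p in range(n_perm):
            rand_idx = rng.choice(n_genes, size=m, replace=False)
            null_d[p], null_c[p] = _module_stats(a_ref, a_test, rand_idx)
        sd_d, sd_c = null_d.std(ddof=1), null_c.std(ddof=1)
        if sd_d == 0 or sd_c == 0:
            warnings.warn(f"degenerate permutation null for module {module}", stacklevel=2)

        def _z(obs: float, null: np.ndarray, sd: float) -> float:
            # degenerate null (e.g. identical networks give connectivity 1
            # for every gene set): observed equal to the null carries no
            # evidence either way -> Z = 0
            if sd > 0:
                return float((obs - null.mean()) / sd)
            return 0.0 if abs(obs - null.mean()) < 1e-12 else float("nan")

        z_d = _z(obs_d, null_d, sd_d)
        z_c = _z(obs_c, null_c, sd_c)
        reports.append(
            PreservationReport(
                module=module,
                size=m,
                z_density=z_d,
                z_connectivity=z_c,
                z_summary=(z_d + z_c) / 2.0,
                observed_density=obs_d,
                observed_connectivity=obs_c,
                null_density_mean=float(null_d.mean()),
                null_density_sd=float(sd_d),
                null_connectivity_mean=float(null_c.mean()),
                null_connectivity_sd=float(sd_c),
                n_permutations=n_perm,
                seed=seed,
            )
        )
    return reports


def read_sample_matrix(
    path: str | Path, sep: str | None = None, standardize: bool = False
) -> SampleMatrix:
    """Read a genes × samples CSV/TSV (header row, gene-name first column)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    sm = SampleMatrix(values=df)
    return sm.standardize() if standardize else sm
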