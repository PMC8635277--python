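"""Single-cell pipeline: QC filtering, log-normalization with covariate
regression, PCA, shared-nearest-neighbor (SNN) clustering with
silhouette-selected resolution, marker and unique-marker calling, and
projection of bulk program gene sets onto cell subtypes.

The QC rules mirror droplet-data practice: cells with <200 genes
detected, <1,000 UMIs, >5% mitochondrial UMIs, or >30,000-UMI doublet-like
outliers are removed, then genes detected in fewer than three remaining
cells are dropped.  The SNN graph weights edges by the Jaccard similarity
of 20-nearest-neighbor sets (pruned below 1/15) and is partitioned by
modularity optimization at a resolution parameter chosen to maximize the
average silhouette width in PC space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples, silhouette_score
from sklearn.neighbors import NearestNeighbors

from .bulk import _seed_int, bh_fdr
from .io import CellMatrix
from .prioritize import detection_fraction

logger = logging.getLogger("rppkit")

QC_RULE_ORDER = ("low_genes", "low_umis", "high_mito", "high_umis")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass
class QCResult:
    """Filtered matrix plus per-rule removal bookkeeping.

    A cell failing several rules is counted once, attributed to the first
    failing rule in the order low_genes, low_umis, high_mito, high_umis.
    """

    cells: CellMatrix
    removed: dict[str, list[str]]  # rule -> barcodes removed under that rule
    n_genes_dropped: int

    @property
    def removed_barcodes(self) -> set[str]:
        return {b for bs in self.removed.values() for b in bs}

    def report(self) -> pd.DataFrame:
        rows = [(rule, len(bs)) for rule, bs in self.removed.items()]
        rows.append(("genes_dropped", self.n_genes_dropped))
        rows.append(("cells_retained", len(self.cells.barcodes)))
        return pd.DataFrame(rows, columns=["rule", "count"]).set_index("rule")


def qc_filter(
    cells: CellMatrix,
    min_genes: int = 200,
    min_umis: int = 1000,
    max_mito: float = 0.05,
    max_umis: int = 30000,
    min_cells_per_gene: int = 3,
) -> QCResult:
    """Drop cells failing any QC rule, then rarely detected genes.

    The rules are strict inequalities (a cell at exactly 200 genes and
    1,000 UMIs is retained): fewer than ``min_genes`` genes detected,
    fewer than ``min_umis`` UMIs, more than ``max_mito`` mitochondrial
    UMI fraction, or more than ``max_umis`` UMIs.
    """
    stats = cells.cell_stats
    fails = {
        "low_genes": stats["n_genes_detected"] < min_genes,
        "low_umis": stats["n_umis"] < min_umis,
        "high_mito": stats["mito_fraction"] > max_mito,
        "high_umis": stats["n_umis"] > max_umis,
    }
    attributed: dict[str, list[str]] = {r: [] for r in QC_RULE_ORDER}
    drop = np.zeros(len(stats), dtype=bool)
    for rule in QC_RULE_ORDER:
        mask = fails[rule].to_numpy() & ~drop
        attributed[rule] = list(stats.index[mask])
        drop |= fails[rule].to_numpy()
    if drop.all():
        breakdown = {r: len(b) for r, b in attributed.items()}
        raise ValueError(f"all cells removed by QC; per-rule breakdown {breakdown}")
    kept = cells.subset(cell_mask=~drop)
    detected_in = kept.X.tocsr().astype(bool).sum(axis=1)
    gene_ok = np.asarray(detected_in).ravel() >= min_cells_per_gene
    n_dropped = int((~gene_ok).sum())
    if n_dropped:
        kept = kept.subset(gene_mask=gene_ok)
    return QCResult(kept, attributed, n_dropped)


# ---------------------------------------------------------------------------
# Normalization and scaling
# ---------------------------------------------------------------------------


@dataclass
class ScaledMatrix:
    """Log-normalized and covariate-regressed, z-scored expression."""

    scaled: np.ndarray  # genes x cells, z-scored residuals clipped at +-10
    lognorm: np.ndarray  # genes x cells log1p(counts per 10k)
    gene_ids: list[str]
    barcodes: list[str]
    cell_stats: pd.DataFrame

    @property
    def shape(self) -> tuple[int, int]:
        return self.scaled.shape


def normalize_scale(
    cells: CellMatrix, covariates: tuple[str, ...] = ("n_umis", "mito_fraction")
) -> ScaledMatrix:
    """Log-normalize, regress out per-cell covariates, and z-score.

    Counts are scaled to 10,000 per cell and log1p-transformed; each
    gene is then fit by ordinary least squares on the (standardized)
    covariates and replaced by its residuals, which are z-scored across
    cells and clipped at +-10.  Genes left with zero variance (e.g.
    expression exactly linear in a covariate) are dropped with a warning,
    as are zero-variance covariates.
    """
    X = cells.X.astype(float).toarray()
    totals = X.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("cell with zero total counts; run qc_filter first")
    lognorm = np.log1p(X / totals * 1e4)

    cols = [np.ones(X.shape[1])]
    for cov in covariates:
        v = cells.cell_stats[cov].to_numpy(dtype=float)
        if v.std() == 0:
            logger.warning("covariate %r has zero variance; dropped", cov)
            continue
        cols.append((v - v.mean()) / v.std())
    D = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(D, lognorm.T, rcond=None)
    resid = lognorm - (D @ beta).T

    sd = resid.std(axis=1, ddof=0)
    keep = sd > 1e-12
    if (~keep).any():
        logger.warning("%d zero-variance gene(s) dropped after scaling", int((~keep).sum()))
    resid = resid[keep]
    scaled = (resid - resid.mean(axis=1, keepdims=True)) / resid.std(
        axis=1, keepdims=True, ddof=0
    )
    scaled = np.clip(scaled, -10.0, 10.0)
    genes = [g for g, k in zip(cells.gene_ids, keep) if k]
    return ScaledMatrix(scaled, lognorm[keep], genes, list(cells.barcodes), cells.cell_stats)


# ---------------------------------------------------------------------------
# Embedding + SNN clustering
# ---------------------------------------------------------------------------


def compute_pcs(sm: ScaledMatrix, n_pcs: int = 30, seed: int = 0) -> np.ndarray:
    """Cell x component PC coordinates with a deterministic sign convention
    (the largest-magnitude loading of each component is made positive)."""
    n_pcs = int(n_pcs)
    if n_pcs >= min(sm.shape):
        raise ValueError(f"n_pcs={n_pcs} must be < min(genes, cells)={min(sm.shape)}")
    pca = PCA(n_components=n_pcs, random_state=_seed_int(seed))
    pcs = pca.fit_transform(sm.scaled.T)
    flip = np.sign(
        pca.components_[np.arange(n_pcs), np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    return pcs * flip


def snn_graph(
    pcs: np.ndarray, n_neighbors: int = 20, prune: float = 1.0 / 15.0
) -> ig.Graph:
    """Shared-nearest-neighbor graph in PC space.

    Each cell's neighbor set is its ``n_neighbors`` nearest cells
    (Euclidean, including itself); edges are weighted by the Jaccard
    similarity of neighbor sets and discarded below ``prune``.
    """
    n = pcs.shape[0]
    if n < n_neighbors + 1:
        raise ValueError(f"need more than n_neighbors={n_neighbors} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(pcs)
    idx = nn.kneighbors(return_distance=False)  # excludes self
    rows = np.repeat(np.arange(n), n_neighbors - 1)
    cols = idx[:, : n_neighbors - 1].ravel()
    A = sp.csr_matrix(
        (np.ones(rows.size + n), (np.concatenate([rows, np.arange(n)]),
                                  np.concatenate([cols, np.arange(n)]))),
        shape=(n, n),
    )
    A.data[:] = 1.0
    inter = (A @ A.T).tocoo()
    mask = inter.row < inter.col
    r, c, shared = inter.row[mask], inter.col[mask], inter.data[mask]
    jacc = shared / (2 * n_neighbors - shared)
    keep = jacc >= prune
    g = ig.Graph(
        n=n, edges=list(zip(r[keep].tolist(), c[keep].tolist())), directed=False
    )
    g.es["weight"] = jacc[keep].tolist()
    return g


@dataclass
class ClusterSolution:
    """One SNN clustering at a given resolution."""

    resolution: float
    labels: pd.Series  # barcode -> contiguous cluster index
    n_clusters: int
    asw: float  # average silhouette width in PC space (NaN if 1 cluster)
    per_cluster_silhouette: pd.Series
    pcs: np.ndarray = field(repr=False)


def _silhouette(
    pcs: np.ndarray, labels: np.ndarray, seed: int, max_cells: int = 5000
) -> tuple[float, pd.Series]:
    if len(np.unique(labels)) < 2:
        return float("nan"), pd.Series(dtype=float)
    if pcs.shape[0] > max_cells:
        rng = np.random.default_rng(_seed_int(seed))
        sub = rng.choice(pcs.shape[0], size=max_cells, replace=False)
        pcs, labels = pcs[sub], labels[sub]
        if len(np.unique(labels)) < 2:
            return float("nan"), pd.Series(dtype=float)
    samples = silhouette_samples(pcs, labels)
    per_cluster = pd.Series(samples).groupby(labels).mean()
    return float(samples.mean()), per_cluster


def cluster_graph(graph: ig.Graph, resolution: float, seed: int = 0) -> np.ndarray:
    """Modularity community detection (Leiden refinement of the Louvain
    objective, RB-configuration null model) at the given resolution."""
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=float(resolution),
        seed=_seed_int(seed),
        n_iterations=-1,
    )
    return np.asarray(part.membership)


def embed_and_cluster(
    sm: ScaledMatrix,
    n_pcs: int = 30,
    n_neighbors: int = 20,
    resolution: float = 0.35,
    seed: int = 0,
    prune: float = 1.0 / 15.0,
) -> ClusterSolution:
    """PCA -> SNN graph -> modularity communities -> silhouette."""
    pcs = compute_pcs(sm, n_pcs, seed)
    graph = snn_graph(pcs, n_neighbors, prune)
    labels = cluster_graph(graph, resolution, seed)
    asw, per_cluster = _silhouette(pcs, labels, seed)
    return ClusterSolution(
        resolution=float(resolution),
        labels=pd.Series(labels, index=sm.barcodes, name="cluster"),
        n_clusters=int(labels.max()) + 1,
        asw=asw,
        per_cluster_silhouette=per_cluster,
        pcs=pcs,
    )


def select_resolution(
    sm: ScaledMatrix,
    resolution_grid=(0.1, 0.2, 0.35, 0.5, 0.8, 1.2),
    n_pcs: int = 30,
    n_neighbors: int = 20,
    seed: int = 0,
    prune: float = 1.0 / 15.0,
) -> tuple[float, dict[float, ClusterSolution], pd.DataFrame]:
    """Cluster at each resolution and pick the ASW-maximal one.

    Resolutions yielding a single cluster have undefined ASW and are
    excluded from the argmax; ties break toward the smaller resolution.
    Returns the chosen resolution, all solutions, and a diagnostics table
    (n_clusters and ASW per resolution).
    """
    grid = sorted(set(float(r) for r in resolution_grid))
    if len(resolution_grid) < 1:
        raise ValueError("resolution grid is empty")
    pcs = compute_pcs(sm, n_pcs, seed)
    graph = snn_graph(pcs, n_neighbors, prune)
    solutions: dict[float, ClusterSolution] = {}
    for res in grid:
        labels = cluster_graph(graph, res, seed)
        asw, per_cluster = _silhouette(pcs, labels, seed)
        solutions[res] = ClusterSolution(
            res,
            pd.Series(labels, index=sm.barcodes, name="cluster"),
            int(labels.max()) + 1,
            asw,
            per_cluster,
            pcs,
        )
    diag = pd.DataFrame(
        {
            "resolution": grid,
            "n_clusters": [solutions[r].n_clusters for r in grid],
            "asw": [solutions[r].asw for r in grid],
        }
    ).set_index("resolution")
    usable = [r for r in grid if solutions[r].n_clusters > 1 and np.isfinite(solutions[r].asw)]
    if not usable:
        raise ValueError("every resolution produced a single cluster; ASW undefined")
    best = max(usable, key=lambda r: (solutions[r].asw, -r))
    return best, solutions, diag


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------


@dataclass
class MarkerTable:
    """Per (cluster, gene) marker statistics."""

    table: pd.DataFrame

    def markers_of(self, cluster: int, unique: bool = False) -> pd.Index:
        t = self.table
        flag = "is_unique_marker" if unique else "is_marker"
        sel = t[(t["cluster"] == cluster) & t[flag]]
        return pd.Index(sel["gene"])


def find_markers(
    sm: ScaledMatrix,
    labels: pd.Series,
    min_pct: float = 0.40,
    min_logfc: float = 0.25,
    unique_pct_in: float = 85.0,
    unique_pct_out: float = 35.0,
    fdr_max: float = 0.05,
) -> MarkerTable:
    """Cluster-versus-rest marker genes.

    Candidates must be expressed in at least ``min_pct`` of the cluster's
    cells and exceed ``min_logfc`` log2 fold change (cluster mean versus
    rest on normalized counts, pseudocount 1); significance is a Wilcoxon
    rank-sum test on log-normalized values with BH correction within the
    cluster.  A marker is *unique* when expressed in more than
    ``unique_pct_in``% of its own cluster and fewer than
    ``unique_pct_out``% of the other cells.
    """
    lab = labels.loc[sm.barcodes].to_numpy()
    uniq = np.unique(lab)
    if uniq.size < 2:
        raise ValueError("need >= 2 clusters to call markers")
    norm = np.expm1(sm.lognorm)  # counts-per-10k scale
    detected = sm.lognorm > 0
    genes = np.asarray(sm.gene_ids)
    frames = []
    for cl in uniq:
        in_mask = lab == cl
        if in_mask.sum() < 2:
            logger.warning("cluster %s has <2 cells; skipped", cl)
            continue
        out_mask = ~in_mask
        pct_in = detected[:, in_mask].mean(axis=1) * 100.0
        pct_out = detected[:, out_mask].mean(axis=1) * 100.0
        lfc = np.log2((norm[:, in_mask].mean(axis=1) + 1.0) / (norm[:, out_mask].mean(axis=1) + 1.0))
        cand = (pct_in >= min_pct * 100.0) & (lfc > min_logfc)
        if not cand.any():
            continue
        pvals = st.mannwhitneyu(
            sm.lognorm[cand][:, in_mask],
            sm.lognorm[cand][:, out_mask],
            axis=1,
            alternative="two-sided",
        ).pvalue
        fdr = bh_fdr(pvals)
        df = pd.DataFrame(
            {
                "cluster": cl,
                "gene": genes[cand],
                "log2fc": lfc[cand],
                "pct_in": pct_in[cand],
                "pct_out": pct_out[cand],
                "pvalue": pvals,
                "fdr": fdr,
            }
        )
        df["is_marker"] = df["fdr"] < fdr_max
        df["is_unique_marker"] = (
            df["is_marker"] & (df["pct_in"] > unique_pct_in) & (df["pct_out"] < unique_pct_out)
        )
        frames.append(df)
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "cluster", "gene", "log2fc", "pct_in", "pct_out",
                "pvalue", "fdr", "is_marker", "is_unique_marker",
            ]
        )
    )
    return MarkerTable(table)


# ---------------------------------------------------------------------------
# Program projection
# ---------------------------------------------------------------------------


@dataclass
class ProjectionResult:
    """Mean program scores per cell and per subtype, plus detection report."""

    cell_scores: pd.DataFrame  # cell x program mean scaled expression
    subtype_means: pd.DataFrame  # subtype x program
    detection_per_set: dict[str, float]
    detection_combined: float
    undetected_sets: list[str]


def program_projection(
    sm: ScaledMatrix, labels: pd.Series, gene_sets: dict[str, list[str]]
) -> ProjectionResult:
    """Average scaled expression of each program's detected genes per cell,
    summarized per subtype, with the fraction of each program detected
    post-QC."""
    if not gene_sets or any(not gs for gs in gene_sets.values()):
        raise ValueError("gene sets must be non-empty")
    gi = {g: i for i, g in enumerate(sm.gene_ids)}
    scores = {}
    undetected = []
    for name, gset in gene_sets.items():
        idx = [gi[g] for g in gset if g in gi]
        if not idx:
            undetected.append(name)
            scores[name] = np.full(len(sm.barcodes), np.nan)
        else:
            scores[name] = sm.scaled[idx].mean(axis=0)
    cell_scores = pd.DataFrame(scores, index=sm.barcodes)
    lab = labels.loc[sm.barcodes]
    subtype_means = cell_scores.groupby(lab).mean()
    per_set, combined = detection_fraction(gene_sets, sm.gene_ids)
    return ProjectionResult(cell_scores, subtype_means, per_set, combined, undetected)
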