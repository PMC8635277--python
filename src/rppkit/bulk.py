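"""Bulk time-course pipeline: CPM filtering, differential expression,
z-scaled trajectories, gap-statistic model selection, k-means clustering
with membership scores, trend classification, and sample dendrograms.

The clustering substrate is the gene x ordered-population matrix of
centred and scaled mean log2(CPM+1) values; the number of clusters is
chosen by the gap statistic (uniform-range reference, 1-SE rule) next to
the between-group-SS elbow curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as hierarchy
import scipy.stats as st
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

logger = logging.getLogger("rppkit")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Normalization and filtering
# ---------------------------------------------------------------------------


@dataclass
class NormalizedMatrix:
    """CPM and log2(CPM+1) values plus the gene filter mask.

    ``reasons`` codes each masked gene as ``low_cpm`` or ``non_coding``;
    masked genes are excluded from every downstream stage.
    """

    cpm: pd.DataFrame
    log2cpm: pd.DataFrame
    keep: pd.Series  # True = gene passes the filter
    reasons: pd.Series  # reason code for masked genes, "" otherwise
    sample_meta: pd.DataFrame
    population_order: list[str]

    @property
    def kept_log2cpm(self) -> pd.DataFrame:
        return self.log2cpm.loc[self.keep]

    def populations(self) -> pd.Series:
        return self.sample_meta.loc[self.cpm.columns, "population"]

    def population_mean_log2cpm(self, kept_only: bool = True) -> pd.DataFrame:
        """Mean log2(CPM+1) per ordered population (replicates averaged)."""
        mat = self.kept_log2cpm if kept_only else self.log2cpm
        pops = self.populations()
        out = {p: mat.loc[:, pops.index[pops == p]].mean(axis=1) for p in self.population_order}
        return pd.DataFrame(out)


def normalize_and_filter(
    cm: CountMatrix, cpm_min: float = 10.0, coding_only: bool = False
) -> NormalizedMatrix:
    """CPM-normalize and mask lowly expressed / non-coding genes.

    CPM = count / column sum * 1e6.  A gene passes the expression filter
    if its maximum population-mean CPM is at least ``cpm_min`` — i.e. it
    is well expressed in at least one state of the time course.  With
    ``coding_only``, genes whose ``gene_type`` is not ``protein_coding``
    are masked as ``non_coding``.
    """
    counts = cm.counts.astype(float)
    colsums = counts.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has an all-zero count column")
    cpm = counts / colsums * 1e6
    log2cpm = np.log2(cpm + 1.0)

    pops = cm.populations()
    pop_mean_cpm = pd.DataFrame(
        {p: cpm.loc[:, pops.index[pops == p]].mean(axis=1) for p in cm.population_order}
    )
    keep = pop_mean_cpm.max(axis=1) >= cpm_min
    reasons = pd.Series("", index=cpm.index, dtype=object)
    reasons[~keep] = "low_cpm"
    if coding_only:
        if cm.gene_meta is None or "gene_type" not in cm.gene_meta.columns:
            raise ValueError("coding_only requires gene_meta with a 'gene_type' column")
        coding = cm.gene_meta.loc[cpm.index, "gene_type"] == "protein_coding"
        reasons[keep & ~coding] = "non_coding"
        keep = keep & coding
    return NormalizedMatrix(
        cpm, log2cpm, keep, reasons, cm.sample_meta, list(cm.population_order)
    )


# ---------------------------------------------------------------------------
# Differential expression (negative binomial likelihood-ratio test)
# ---------------------------------------------------------------------------


@dataclass
class DETable:
    """Per-gene DE results for one two-group comparison."""

    table: pd.DataFrame  # log2fc, pvalue, fdr, direction, is_de
    group_a: list[str]
    group_b: list[str]
    test: str = "nb_lrt"

    @property
    def de_genes(self) -> pd.Index:
        return self.table.index[self.table["is_de"]]


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, normalized to geometric mean 1."""
    positive = (counts > 0).all(axis=1)
    if positive.sum() >= 10:
        log_ref = np.log(counts[positive]).mean(axis=1, keepdims=True)
        log_sf = np.median(np.log(counts[positive]) - log_ref, axis=0)
    else:  # fallback: column sums
        colsums = counts.sum(axis=0)
        log_sf = np.log(colsums)
    log_sf = log_sf - log_sf.mean()
    return np.exp(log_sf)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    n = 1.0 / alpha
    p = n / (n + np.maximum(mu, 1e-9))
    return float(st.nbinom.logpmf(np.round(y), n, p).sum())


def de_test(
    nm: NormalizedMatrix,
    cm: CountMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
    fc_min: float = 1.5,
    fdr_max: float = 0.05,
) -> DETable:
    """Gene-wise negative binomial likelihood-ratio test between two groups.

    Counts are library-size normalized with median-of-ratios size factors
    (each sample's median ratio to the gene-wise geometric-mean reference,
    robust to a minority of truly changing genes; column-sum factors are
    the fallback when too few genes are positive throughout).  Gene-wise
    dispersion is estimated by the method of moments from within-group
    variability and floored at 0.01.
    The null model shares one mean across both groups; the alternative
    fits a mean per group.  A gene is flagged DE iff
    ``|log2FC| >= log2(fc_min)`` and BH-adjusted p < ``fdr_max``.
    ``log2fc`` is group_b relative to group_a.
    """
    a, b = list(group_a), list(group_b)
    if set(a) & set(b):
        raise ValueError(f"groups overlap: {sorted(set(a) & set(b))}")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    genes = nm.keep[nm.keep].index
    counts = cm.counts.loc[genes, a + b].to_numpy(dtype=float)
    sf = _size_factors(counts)
    norm = counts / sf  # library-size normalized counts
    na = len(a)
    ya, yb = norm[:, :na], norm[:, na:]
    qa, qb = ya.mean(axis=1), yb.mean(axis=1)
    q0 = norm.mean(axis=1)

    # pooled within-group method-of-moments dispersion, floored
    va = ya.var(axis=1, ddof=1)
    vb = yb.var(axis=1, ddof=1)
    pooled_var = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
    m = np.maximum(norm.mean(axis=1), 1e-9)
    alpha = np.maximum((pooled_var - m) / m**2, 0.01)

    stat = np.empty(len(genes))
    for i in range(len(genes)):
        mu_null = q0[i] * sf
        mu_alt = np.concatenate([np.full(na, qa[i]), np.full(len(b), qb[i])]) * sf
        ll0 = _nb_loglik(counts[i], mu_null, alpha[i])
        ll1 = _nb_loglik(counts[i], mu_alt, alpha[i])
        stat[i] = max(0.0, 2.0 * (ll1 - ll0))
    pvals = st.chi2.sf(stat, df=1)
    pvals[stat == 0.0] = 1.0
    fdr = bh_fdr(pvals)
    pc = 0.5
    log2fc = np.log2((qb + pc) / (qa + pc))
    is_de = (np.abs(log2fc) >= np.log2(fc_min)) & (fdr < fdr_max)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "is_de": is_de,
        },
        index=genes,
    )
    return DETable(table, a, b)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryMatrix:
    """Gene x ordered-population z-scaled mean log2 expression."""

    Z: pd.DataFrame  # rows mean 0, sd 1
    population_order: list[str]
    row_mean: pd.Series  # pre-scaling mean, retained for reporting
    row_sd: pd.Series

    @property
    def gene_ids(self) -> pd.Index:
        return self.Z.index


def build_trajectories(
    nm: NormalizedMatrix, population_order: Sequence[str] | None = None
) -> TrajectoryMatrix:
    """Average log2(CPM+1) within each population, then z-score per gene.

    Genes constant across populations (z undefined) are dropped with a
    warning.
    """
    pops = list(population_order or nm.population_order)
    if len(pops) < 3:
        raise ValueError("need >= 3 ordered populations")
    sample_pops = nm.populations()
    for p in pops:
        if not (sample_pops == p).any():
            raise ValueError(f"population {p!r} has no samples")
    means = nm.population_mean_log2cpm()[pops]
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant gene(s) dropped from trajectories (z undefined)",
            int(constant.sum()),
        )
    means = means.loc[~constant]
    Z = means.sub(mu[~constant], axis=0).div(sd[~constant], axis=0)
    return TrajectoryMatrix(Z, pops, mu[~constant], sd[~constant])


# ---------------------------------------------------------------------------
# Model selection: gap statistic + elbow
# ---------------------------------------------------------------------------


def _seed_int(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0] % (2**32 - 1))
    return int(seed) % (2**32 - 1)


def _best_kmeans(X: np.ndarray, k: int, n_init: int, seed) -> KMeans:
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=300,
        tol=1e-6,
        random_state=_seed_int(seed),
    )
    km.fit(X)
    return km


def select_k(
    tm: TrajectoryMatrix,
    k_range: Iterable[int] = range(2, 13),
    B: int = 50,
    seed: int = 0,
    n_init: int = 25,
    ref_n_init: int = 5,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of k-means clusters by the gap statistic.

    For each k, ``W_k`` is the best-of-``n_init`` within-cluster sum of
    squares; ``Gap(k) = mean_b log W*_kb - log W_k`` against B reference
    data sets drawn uniformly over each feature's observed range, with
    ``s_k = sd_b(log W*_kb) * sqrt(1 + 1/B)``.  The 1-SE rule returns the
    smallest k with ``Gap(k) >= Gap(k+1) - s_{k+1}``.  Reference fits use
    ``ref_n_init`` restarts (the reference surface is unimodal enough that
    full restarts would only cost time).  The between-group-SS elbow curve
    is included in the diagnostics.
    """
    X = tm.Z.to_numpy()
    ks = sorted(set(int(k) for k in k_range))
    if ks[0] < 2:
        raise ValueError("k_range must start at >= 2")
    if ks[-1] >= X.shape[0]:
        raise ValueError(f"k_range upper bound {ks[-1]} >= number of genes {X.shape[0]}")
    if B < 10:
        raise ValueError("B must be >= 10")
    ss = np.random.SeedSequence(seed)
    data_seeds = ss.spawn(len(ks))
    ref_ss = ss.spawn(1)[0]
    rng = np.random.default_rng(ref_ss)
    lo, hi = X.min(axis=0), X.max(axis=0)
    tss = float(((X - X.mean(axis=0)) ** 2).sum())

    logW = np.empty(len(ks))
    bss = np.empty(len(ks))
    gap = np.empty(len(ks))
    s = np.empty(len(ks))
    ref_sets = [rng.uniform(lo, hi, size=X.shape) for _ in range(B)]
    ref_seeds = ref_ss.spawn(B * len(ks))
    for i, k in enumerate(ks):
        km = _best_kmeans(X, k, n_init, data_seeds[i])
        W = max(km.inertia_, 1e-12)
        logW[i] = np.log(W)
        bss[i] = tss - km.inertia_
        ref_logW = np.empty(B)
        for b in range(B):
            rkm = _best_kmeans(ref_sets[b], k, ref_n_init, ref_seeds[i * B + b])
            ref_logW[b] = np.log(max(rkm.inertia_, 1e-12))
        gap[i] = ref_logW.mean() - logW[i]
        s[i] = ref_logW.std(ddof=0) * np.sqrt(1.0 + 1.0 / B)

    k_star = None
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            k_star = ks[i]
            break
    if k_star is None:
        logger.warning("gap 1-SE rule never satisfied; returning the largest k tried")
        k_star = ks[-1]
    diag = pd.DataFrame(
        {"k": ks, "log_wcss": logW, "between_ss": bss, "gap": gap, "gap_se": s}
    ).set_index("k")
    return k_star, diag


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

TREND_LABELS = ("monotone_up", "monotone_down", "transient_up", "transient_down", "mixed")


def classify_trend(centroid: Sequence[float], eps: float = 0.1) -> str:
    """Label a centroid's shape over the ordered populations.

    Successive differences of magnitude at most ``eps`` (z units) are
    flat steps.
    All non-flat steps positive -> monotone_up; all negative ->
    monotone_down; a single sign reversal with an interior global extremum
    -> transient_up/down; anything else (including all-flat) -> mixed.
    Adding a constant to the centroid does not change the label.
    """
    c = np.asarray(centroid, dtype=float)
    if c.size < 3:
        raise ValueError("centroid needs >= 3 populations")
    d = np.diff(c)
    signs = [int(np.sign(x)) for x in d if abs(x) > eps]
    if not signs:
        return "mixed"
    if all(x > 0 for x in signs):
        return "monotone_up"
    if all(x < 0 for x in signs):
        return "monotone_down"
    collapsed = [signs[0]]
    for x in signs[1:]:
        if x != collapsed[-1]:
            collapsed.append(x)
    if collapsed == [1, -1] and 0 < int(np.argmax(c)) < c.size - 1:
        return "transient_up"
    if collapsed == [-1, 1] and 0 < int(np.argmin(c)) < c.size - 1:
        return "transient_down"
    return "mixed"


@dataclass
class ClusterModel:
    """A k-means solution over gene trajectories."""

    k: int
    assignments: pd.Series  # gene -> cluster index (0..k-1)
    centroids: pd.DataFrame  # cluster x ordered population
    membership: pd.Series  # Pearson correlation of each gene with its centroid
    trends: dict[int, str]
    inertia: float
    diagnostics: pd.DataFrame | None = None

    def genes_in(self, cluster: int) -> pd.Index:
        return self.assignments.index[self.assignments == cluster]

    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def cluster_trajectories(
    tm: TrajectoryMatrix, k: int, seed: int = 0, n_init: int = 25, trend_eps: float = 0.1
) -> ClusterModel:
    """k-means (k-means++ init, best of ``n_init`` restarts) on z trajectories.

    The membership score of a gene is the Pearson correlation between its
    z row and its own cluster centroid, the quantity used to shade genes
    by how well they match the cluster core.
    """
    X = tm.Z.to_numpy()
    if not 2 <= k < X.shape[0]:
        raise ValueError(f"k={k} outside [2, n_genes)")
    km = _best_kmeans(X, k, n_init, seed)
    labels = km.labels_
    sizes = np.bincount(labels, minlength=k)
    if (sizes == 0).any():
        raise RuntimeError("k-means converged with an empty cluster in every restart")
    centroids = km.cluster_centers_

    C = centroids[labels]
    Xc = X - X.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(Cc, axis=1)
    membership = (Xc * Cc).sum(axis=1) / np.where(denom == 0, np.nan, denom)

    cent = pd.DataFrame(centroids, columns=tm.population_order)
    trends = {i: classify_trend(centroids[i], trend_eps) for i in range(k)}
    return ClusterModel(
        k=k,
        assignments=pd.Series(labels, index=tm.Z.index, name="cluster"),
        centroids=cent,
        membership=pd.Series(membership, index=tm.Z.index, name="membership_score"),
        trends=trends,
        inertia=float(km.inertia_),
    )


# ---------------------------------------------------------------------------
# Sample relationships
# ---------------------------------------------------------------------------


def sample_distance_tree(nm: NormalizedMatrix) -> tuple[np.ndarray, list[str]]:
    """Average-linkage dendrogram on 1 - Spearman correlation of samples.

    Distances are computed between sample log2 CPM profiles over the
    filter-passing genes; returns the SciPy linkage table and the sample
    ids in leaf order of the input columns.
    """
    mat = nm.kept_log2cpm
    if mat.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    rho = st.spearmanr(mat.to_numpy()).statistic
    rho = np.atleast_2d(rho)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    return Z, list(mat.columns)
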