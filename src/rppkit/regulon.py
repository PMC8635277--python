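"""AUCell-style regulon activity scoring and binarization.

A regulon (a transcription factor plus its direct target set, supplied as
a GMT line) is scored in each cell by the area under its rank-recovery
curve within the top fraction of that cell's expression ranking; scores
are binarized per regulon by the intersection point of a two-component
Gaussian mixture over the cell population.  Regulon inference itself is
out of scope: regulons arrive as inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .bulk import _seed_int
from .io import CellMatrix, GeneSetCollection

logger = logging.getLogger("rppkit")


@dataclass
class Regulon:
    """A transcription factor and its direct target genes."""

    tf: str
    targets: list[str]
    note: str = ""

    def gene_set(self, include_tf: bool = True) -> list[str]:
        genes = list(dict.fromkeys(self.targets))
        if include_tf and self.tf not in genes:
            genes = [self.tf, *genes]
        return genes


def regulons_from_gmt(collection: GeneSetCollection) -> list[Regulon]:
    """One regulon per GMT line: set name = TF, members = targets."""
    return [
        Regulon(tf, genes, collection.descriptions.get(tf, ""))
        for tf, genes in collection.items()
    ]


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _recovery_auc(positions: np.ndarray, k: int, m: int) -> float:
    """AUC of the recovery curve r(i), i=1..k, normalized by its maximum.

    ``positions`` are the 0-based ranks of the regulon genes in the cell's
    descending expression order; ``m`` is the regulon size in the gene
    universe.  Sum_i r(i) counts, for each regulon gene at 1-based rank
    q <= k, the k - q + 1 prefix lengths that include it; the maximum is
    attained when the regulon occupies ranks 1..min(m, k).
    """
    q = positions[positions < k] + 1  # 1-based ranks inside the top k
    total = float((k - q + 1).sum())
    max_total = float(sum(min(i, m) for i in range(1, k + 1)))
    return total / max_total if max_total else 0.0


def aucell_score(
    expression: np.ndarray,
    regulon_indices: np.ndarray,
    top_fraction: float = 0.05,
    tie_perm: np.ndarray | None = None,
) -> float:
    """Score one cell: rank genes by descending expression and measure how
    early the regulon's genes are recovered within the top
    ``top_fraction`` of ranks.  Ties (abundant zeros in sparse data) are
    broken by ``tie_perm``, a per-cell permutation fixed by the global
    seed, so the score is deterministic."""
    expression = np.asarray(expression, dtype=float).ravel()
    n = expression.size
    k = math.ceil(top_fraction * n)
    if tie_perm is None:
        tie_perm = np.arange(n)
    order = np.lexsort((tie_perm, -expression))
    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)
    return _recovery_auc(pos[np.asarray(regulon_indices)], k, len(regulon_indices))


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------


def _gaussian_intersection(m1, s1, m2, s2) -> float | None:
    """Intersection of two Gaussian densities between their means."""
    s1, s2 = max(s1, 1e-9), max(s2, 1e-9)
    if abs(s1 - s2) < 1e-12:
        return (m1 + m2) / 2.0
    a = 1.0 / (2 * s1**2) - 1.0 / (2 * s2**2)
    b = m2 / s2**2 - m1 / s1**2
    c = m1**2 / (2 * s1**2) - m2**2 / (2 * s2**2) + math.log(s2 / s1)
    disc = b**2 - 4 * a * c
    if disc < 0:
        return None
    roots = [(-b + s * math.sqrt(disc)) / (2 * a) for s in (1.0, -1.0)]
    lo, hi = min(m1, m2), max(m1, m2)
    inside = [r for r in roots if lo <= r <= hi]
    return inside[0] if inside else None


def binarize(activity: np.ndarray, seed: int = 0) -> tuple[float, np.ndarray]:
    """Threshold one regulon's AUC distribution into on/off calls.

    A two-component 1-D Gaussian mixture is fit by EM (seeded); the
    threshold is the density intersection between the component means,
    falling back to mean + 2 sd of the lower component when the
    components overlap too much for a crossing to exist between them.
    A degenerate (constant) distribution yields all-off with a +inf
    sentinel threshold.  Cells are 'on' where AUC >= threshold; the
    threshold does not depend on cell order.
    """
    x = np.asarray(activity, dtype=float).ravel()
    if x.size < 20:
        raise ValueError("binarize needs >= 20 cells")
    if np.allclose(x, x[0]):
        logger.warning("degenerate activity distribution; all cells off")
        return float("inf"), np.zeros(x.size, dtype=bool)
    order = np.argsort(x, kind="stable")  # fit on sorted values: order-invariant
    gm = GaussianMixture(
        n_components=2,
        random_state=_seed_int(seed),
        n_init=3,
        max_iter=500,
        reg_covar=1e-9,
    ).fit(x[order].reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    lo, hi = np.argsort(means)
    thr = _gaussian_intersection(means[lo], sds[lo], means[hi], sds[hi])
    if thr is None or not means[lo] <= thr <= means[hi]:
        thr = float(means[lo] + 2.0 * sds[lo])
    return float(thr), x >= thr


# ---------------------------------------------------------------------------
# Full activity matrix
# ---------------------------------------------------------------------------


@dataclass
class ActivityMatrix:
    """Cell x regulon AUC scores with binarized on/off calls."""

    auc: pd.DataFrame  # cells x regulons, values in [0, 1]
    binary: pd.DataFrame  # same shape, boolean
    thresholds: dict[str, float] = field(default_factory=dict)

    def on_fraction_by(self, labels: pd.Series) -> pd.DataFrame:
        """Fraction of cells 'on' per cluster (the display summary)."""
        lab = labels.loc[self.binary.index]
        return self.binary.groupby(lab).mean()


def regulon_matrix(
    cells: CellMatrix,
    regulons: list[Regulon],
    top_fraction: float = 0.05,
    seed: int = 0,
    include_tf: bool = True,
) -> ActivityMatrix:
    """Score every regulon in every cell, then binarize per regulon.

    Regulons with fewer than two genes in the matrix's gene universe are
    skipped with a warning.  Per-cell tie-break permutations and the EM
    binarization are derived from ``seed``, so results are reproducible
    and invariant to cell order.
    """
    gi = {g: i for i, g in enumerate(cells.gene_ids)}
    usable: list[tuple[str, np.ndarray]] = []
    for reg in regulons:
        idx = np.array([gi[g] for g in reg.gene_set(include_tf) if g in gi])
        if idx.size < 2:
            logger.warning("regulon %r has <2 genes in the matrix; skipped", reg.tf)
            continue
        usable.append((reg.tf, idx))
    if not usable:
        raise ValueError("no usable regulon (need >= 2 genes present each)")

    n_genes, n_cells = cells.shape
    X = cells.X.tocsc()
    root = np.random.SeedSequence(seed)
    # per-cell permutations are keyed by barcode so cell order cannot matter
    auc = np.empty((n_cells, len(usable)))
    for j, bc in enumerate(cells.barcodes):
        bc_seed = np.random.SeedSequence(
            [seed, int.from_bytes(bc.encode()[:8].ljust(8, b"\0"), "little")]
        )
        perm = np.random.default_rng(bc_seed).permutation(n_genes)
        expr = np.asarray(X[:, j].todense()).ravel()
        order = np.lexsort((perm, -expr))
        pos = np.empty(n_genes, dtype=np.int64)
        pos[order] = np.arange(n_genes)
        k = math.ceil(top_fraction * n_genes)
        for r, (tf, idx) in enumerate(usable):
            auc[j, r] = _recovery_auc(pos[idx], k, idx.size)

    auc_df = pd.DataFrame(auc, index=cells.barcodes, columns=[tf for tf, _ in usable])
    thresholds: dict[str, float] = {}
    binary = {}
    for tf in auc_df.columns:
        thr, calls = binarize(auc_df[tf].to_numpy(), seed=_seed_int(root.spawn(1)[0]))
        thresholds[tf] = thr
        binary[tf] = calls
    bin_df = pd.DataFrame(binary, index=cells.barcodes)
    return ActivityMatrix(auc_df, bin_df, thresholds)
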