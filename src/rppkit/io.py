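"""Readers and writers for the formats the pipeline consumes.

Tabular count matrices (TSV/CSV with a gene-id first column), 10x-style
MatrixMarket triplets (matrix.mtx + features/barcodes, 1-based on disk,
0-based in memory), GMT gene-set files, and a flat ``key: value`` run
configuration.  All readers reject malformed input rather than repairing
it silently; every writer produces files its paired reader accepts.
"""

from __future__ import annotations

import io as _io
import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("rppkit")

#: ordered populations of the monocyte -> repair-macrophage time course
DEFAULT_POPULATION_ORDER = (
    "mono_d0",
    "ly6c_hi_d1",
    "ly6c_hi_d2",
    "ly6c_lo_d2",
    "ly6c_lo_d4",
)

MITO_PREFIX = "mt-"  # mouse mitochondrial gene nomenclature, matched case-insensitively


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# CountMatrix (bulk entry point)
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts with sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample id.
    sample_meta
        DataFrame indexed by sample id with at least a ``population``
        column; ``time`` and ``replicate`` are carried through if present.
    population_order
        Explicit ordering of population labels along the time course.
        Never inferred from string sort.
    gene_meta
        Optional per-gene annotation (e.g. ``gene_type``).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    population_order: Sequence[str] = DEFAULT_POPULATION_ORDER
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts.index = self.counts.index.astype(str).str.strip()
        self.counts.columns = self.counts.columns.astype(str).str.strip()
        self.population_order = list(self.population_order)
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise FormatError("count matrix contains non-finite values")
        if (vals < 0).any():
            raise FormatError("count matrix contains negative values")
        if "population" not in self.sample_meta.columns:
            raise FormatError("sample metadata lacks a 'population' column")
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise FormatError(f"samples missing from metadata: {missing}")
        unknown = set(self.sample_meta.loc[self.counts.columns, "population"]) - set(
            self.population_order
        )
        if unknown:
            raise FormatError(
                f"populations {sorted(unknown)} not in declared order "
                f"{list(self.population_order)}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def populations(self) -> pd.Series:
        """Population label per sample, in column order."""
        return self.sample_meta.loc[self.counts.columns, "population"]

    def samples_of(self, population: str) -> list[str]:
        pops = self.populations()
        return list(pops.index[pops == population])


def _check_unique(index: pd.Index, what: str) -> None:
    dup = index[index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate {what} id: {dup[0]!r}")


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_count_matrix(
    path: str | Path,
    meta_path: str | Path,
    population_order: Sequence[str] = DEFAULT_POPULATION_ORDER,
    gene_meta_path: str | Path | None = None,
) -> CountMatrix:
    """Read a delimited gene x sample count matrix plus its sample metadata.

    The matrix has a header row of sample ids and gene ids in the first
    column; the metadata table is keyed by sample id.  Duplicated ids,
    samples absent from the metadata, and non-numeric cells are hard
    errors naming the offender.
    """
    path, meta_path = Path(path), Path(meta_path)
    raw = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.strip()
    _check_unique(raw.index, "gene")
    _check_unique(pd.Index(raw.columns), "sample")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell {raw.iat[r, c]!r} at gene {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        raise FormatError("count matrix contains empty cells")
    meta = pd.read_csv(meta_path, sep=_sniff_sep(meta_path), index_col=0)
    meta.index = meta.index.astype(str).str.strip()
    gene_meta = None
    if gene_meta_path is not None:
        gene_meta_path = Path(gene_meta_path)
        gene_meta = pd.read_csv(gene_meta_path, sep=_sniff_sep(gene_meta_path), index_col=0)
        gene_meta.index = gene_meta.index.astype(str).str.strip()
    return CountMatrix(numeric, meta, population_order, gene_meta)


def write_count_matrix(cm: CountMatrix, path: str | Path, meta_path: str | Path) -> None:
    counts = cm.counts
    if np.allclose(counts.to_numpy(), np.round(counts.to_numpy())):
        counts = counts.astype(np.int64)
    counts.to_csv(path, sep="\t", index_label="gene_id")
    cm.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# CellMatrix (single-cell entry point)
# ---------------------------------------------------------------------------


@dataclass
class CellMatrix:
    """Sparse gene x cell counts with per-cell QC statistics.

    ``cell_stats`` (n_genes_detected, n_umis, mito_fraction) is computed
    from the counts at construction; mitochondrial genes are identified by
    the ``mt-`` prefix, case-insensitively.
    """

    X: sp.csr_matrix
    gene_ids: list[str]
    barcodes: list[str]
    cell_stats: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.barcodes = [str(b).strip() for b in self.barcodes]
        n_genes, n_cells = self.X.shape
        if n_genes != len(self.gene_ids):
            raise FormatError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} feature ids"
            )
        if n_cells != len(self.barcodes):
            raise FormatError(
                f"matrix has {n_cells} columns but {len(self.barcodes)} barcodes"
            )
        _check_unique(pd.Index(self.gene_ids), "gene")
        _check_unique(pd.Index(self.barcodes), "barcode")
        data = self.X.data
        if data.size and (data < 0).any():
            raise FormatError("negative count entries")
        if data.size and not np.allclose(data, np.round(data)):
            raise FormatError("fractional count entries")
        self.cell_stats = self._compute_stats()

    def _compute_stats(self) -> pd.DataFrame:
        csc = self.X.tocsc()
        n_umis = np.asarray(csc.sum(axis=0)).ravel()
        n_genes = csc.getnnz(axis=0)
        mito_mask = np.array(
            [g.lower().startswith(MITO_PREFIX) for g in self.gene_ids], dtype=bool
        )
        mito_umis = (
            np.asarray(csc[mito_mask].sum(axis=0)).ravel()
            if mito_mask.any()
            else np.zeros_like(n_umis)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(n_umis > 0, mito_umis / np.maximum(n_umis, 1), 0.0)
        return pd.DataFrame(
            {
                "n_genes_detected": n_genes,
                "n_umis": n_umis,
                "mito_fraction": mito_frac,
            },
            index=pd.Index(self.barcodes, name="barcode"),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    @property
    def nnz(self) -> int:
        return self.X.nnz

    def densify(self) -> pd.DataFrame:
        return pd.DataFrame(self.X.toarray(), index=self.gene_ids, columns=self.barcodes)

    def subset(self, gene_mask=None, cell_mask=None) -> "CellMatrix":
        X = self.X
        genes, cells = self.gene_ids, self.barcodes
        if gene_mask is not None:
            gene_mask = np.asarray(gene_mask)
            X = X[gene_mask]
            genes = [g for g, m in zip(genes, gene_mask) if m]
        if cell_mask is not None:
            cell_mask = np.asarray(cell_mask)
            X = X[:, cell_mask]
            cells = [b for b, m in zip(cells, cell_mask) if m]
        return CellMatrix(X.tocsr(), genes, cells)


def _read_id_column(path: str | Path) -> list[str]:
    # features.tsv / barcodes.tsv: one record per line, id in the first field
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0].strip())
    return ids


def read_mtx_triplet(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> CellMatrix:
    """Read a 10x-style MatrixMarket triplet into a sparse gene x cell matrix.

    Indices are 1-based on disk (MatrixMarket convention) and converted to
    the internal 0-based convention.  Header dimensions inconsistent with
    the features/barcodes tables, out-of-range indices, and negative or
    fractional entries are hard errors.
    """
    try:
        M = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # index out of bounds, malformed header, ...
        raise FormatError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    M = sp.coo_matrix(M)
    if M.row.size and (M.row.min() < 0 or M.col.min() < 0):
        raise FormatError(f"{mtx_path}: index below the 1-based MatrixMarket minimum")
    genes = _read_id_column(features_path)
    cells = _read_id_column(barcodes_path)
    if M.shape != (len(genes), len(cells)):
        raise FormatError(
            f"MTX header declares {M.shape} but features/barcodes give "
            f"({len(genes)}, {len(cells)})"
        )
    return CellMatrix(M.tocsr(), genes, cells)


def write_mtx_triplet(
    cells: CellMatrix,
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    coo = cells.X.tocoo()
    if np.allclose(coo.data, np.round(coo.data)):
        coo = coo.astype(np.int64)
    scipy.io.mmwrite(str(mtx_path), coo, field="integer")
    Path(features_path).write_text("".join(f"{g}\n" for g in cells.gene_ids))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in cells.barcodes))


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets parsed from a GMT file."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then member genes.

    Duplicate genes within a line are deduplicated with a logged warning;
    a duplicated set name or a line with no genes is a hard error.  An
    empty file yields an empty collection.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has no genes")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: GMT line has no genes")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "gene set %r: %d duplicate gene(s) removed",
                    name,
                    len(genes) - len(deduped),
                )
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All pipeline thresholds with their defaults.

    Bulk stage: CPM filter, DE gates, k-range for the gap statistic.
    Screen: similarity and labeling cutoffs.  Single-cell stage: QC
    thresholds, covariates, PCA/SNN/marker parameters.  Regulon stage:
    AUCell top fraction.  A global random seed is always set.
    """

    # bulk
    cpm_min: float = 10.0
    fc_min: float = 1.5
    fdr_max: float = 0.05
    k_min: int = 2
    k_max: int = 12
    gap_B: int = 50
    n_init: int = 25
    population_order: tuple[str, ...] = DEFAULT_POPULATION_ORDER
    # trajectory screen
    similarity_min: float = 0.9
    label_similarity: float = 0.93
    label_log2cpm: float = 7.5
    # prioritization
    expr_min_log2cpm: float = 7.5
    n_top: int = 50
    enrich_background: int = 25000
    # single cell QC
    min_genes: int = 200
    min_umis: int = 1000
    max_mito: float = 0.05
    max_umis: int = 30000
    min_cells_per_gene: int = 3
    # single cell embedding / clustering
    n_pcs: int = 30
    n_neighbors: int = 20
    snn_prune: float = 1.0 / 15.0
    resolution_grid: tuple[float, ...] = (0.1, 0.2, 0.35, 0.5, 0.8, 1.2)
    # markers
    marker_min_pct: float = 0.40
    marker_min_logfc: float = 0.25
    unique_pct_in: float = 85.0
    unique_pct_out: float = 35.0
    # regulon activity
    aucell_top_fraction: float = 0.05
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        self.population_order = tuple(self.population_order)
        self.resolution_grid = tuple(self.resolution_grid)
        checks = [
            (self.cpm_min >= 0, "cpm_min must be >= 0"),
            (self.fc_min >= 1, "fc_min must be >= 1"),
            (0 < self.fdr_max <= 1, "fdr_max must be in (0, 1]"),
            (2 <= self.k_min <= self.k_max, "need 2 <= k_min <= k_max"),
            (self.gap_B >= 10, "gap_B must be >= 10"),
            (-1 <= self.similarity_min <= 1, "similarity_min outside [-1, 1]"),
            (-1 <= self.label_similarity <= 1, "label_similarity outside [-1, 1]"),
            (0 <= self.max_mito <= 1, "max_mito must be a fraction in [0, 1]"),
            (self.min_umis <= self.max_umis, "min_umis exceeds max_umis"),
            (self.n_pcs >= 2, "n_pcs must be >= 2"),
            (self.n_neighbors >= 2, "n_neighbors must be >= 2"),
            (0 <= self.snn_prune < 1, "snn_prune must be in [0, 1)"),
            (len(self.resolution_grid) >= 1, "resolution_grid is empty"),
            (0 < self.aucell_top_fraction <= 1, "aucell_top_fraction in (0, 1]"),
            (0 <= self.marker_min_pct <= 1, "marker_min_pct is a fraction"),
            (self.seed is not None and int(self.seed) >= 0, "seed must be set"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {msg}")
        self.seed = int(self.seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, Mapping):
            raise FormatError(f"{path}: config must be a flat key: value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        """Emit the fully resolved configuration (for run reproducibility)."""
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        Path(path).write_text(yaml.safe_dump(out, sort_keys=False))

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
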