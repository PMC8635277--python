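"""Effector-candidate prioritization, overlap statistics, and
hypergeometric gene-set enrichment.

Candidates must be differentially expressed, belong to a target
trajectory cluster (the steadily changing repair/monocyte programs), and
be highly expressed; the secretome flag is joined from a user-supplied
GMT set (VerSeDa-style).  Overlap percentages round half-up and
detection fractions truncate toward zero at the reported precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .bulk import ClusterModel, DETable, NormalizedMatrix, bh_fdr
from .io import GeneSetCollection


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _truncate(x: float, decimals: int) -> float:
    scale = 10**decimals
    # nudge by one ulp so exact decimal boundaries are not cut down by
    # binary floating point (e.g. 100.0 staying 100.0)
    return float(np.floor(x * scale + 1e-9) / scale)


def overlap_stats(list_a: Iterable[str], list_b: Iterable[str]) -> tuple[int, float]:
    """Intersection size of A and B, and the overlap as a percentage of B.

    The percentage is rounded half-up to one decimal (766 of 952 -> 80.5).
    """
    A, B = set(list_a), set(list_b)
    if not A or not B:
        raise ValueError("overlap_stats requires non-empty gene sets")
    n = len(A & B)
    return n, _round_half_up(100.0 * n / len(B), 1)


def detection_fraction(
    gene_sets: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
    detected: Iterable[str],
) -> tuple[dict[str, float], float]:
    """Fraction of each gene set present in ``detected``, plus the pooled total.

    Per-set percentages are reported to one decimal and the combined
    percentage (pooled numerators over pooled denominators) to two,
    truncated toward zero — the convention under which 700/716 prints as
    97.7 and (700+936)/(716+952) as 98.08.
    """
    det = set(detected)
    if isinstance(gene_sets, Mapping):
        items = list(gene_sets.items())
    else:
        items = [(f"set_{i + 1}", s) for i, s in enumerate(gene_sets)]
    per_set: dict[str, float] = {}
    num = den = 0
    for name, genes in items:
        gs = set(genes)
        if not gs:
            raise ValueError(f"gene set {name!r} is empty")
        hit = len(gs & det)
        per_set[name] = _truncate(100.0 * hit / len(gs), 1)
        num += hit
        den += len(gs)
    combined = _truncate(100.0 * num / den, 2)
    return per_set, combined


@dataclass
class CandidateTable:
    """Ranked effector candidates with their gate criteria."""

    table: pd.DataFrame
    target_clusters: tuple[int, ...]

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def prioritize(
    de: DETable,
    model: ClusterModel,
    nm: NormalizedMatrix,
    target_clusters: Iterable[int],
    secretome: GeneSetCollection | None = None,
    secretome_set: str | None = None,
    expr_min_log2cpm: float = 7.5,
    n_top: int = 50,
) -> CandidateTable:
    """Rank genes that are DE, in a target cluster, and highly expressed.

    The composite rank is ``membership_score * |log2FC|`` descending
    (cluster fidelity times effect size), ties broken alphabetically by
    gene id; the top ``n_top`` are returned with an ``is_secreted`` flag
    joined from the named secretome gene set.
    """
    targets = tuple(sorted(int(c) for c in target_clusters))
    secreted: set[str] = set()
    if secretome_set is not None:
        if secretome is None or secretome_set not in secretome:
            raise KeyError(f"secretome set {secretome_set!r} absent from collection")
        secreted = set(secretome[secretome_set])

    genes = model.assignments.index.intersection(de.table.index)
    pop_max = nm.population_mean_log2cpm().loc[genes].max(axis=1)
    pop_peak = nm.population_mean_log2cpm().loc[genes].idxmax(axis=1)
    tab = pd.DataFrame(
        {
            "cluster": model.assignments.loc[genes],
            "membership_score": model.membership.loc[genes],
            "log2fc": de.table.loc[genes, "log2fc"],
            "is_de": de.table.loc[genes, "is_de"],
            "max_log2cpm": pop_max,
            "peak_population": pop_peak,
        }
    )
    tab["in_cluster"] = tab["cluster"].isin(targets)
    tab["high_expression"] = tab["max_log2cpm"] >= expr_min_log2cpm
    tab["is_secreted"] = tab.index.isin(secreted)
    qualified = tab[tab["is_de"] & tab["in_cluster"] & tab["high_expression"]].copy()
    qualified["rank_score"] = qualified["membership_score"] * qualified["log2fc"].abs()
    order = np.lexsort(
        (qualified.index.to_numpy(), -qualified["rank_score"].to_numpy())
    )
    qualified = qualified.iloc[order].head(n_top)
    return CandidateTable(qualified, targets)


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of a query against a gene-set collection."""

    table: pd.DataFrame  # overlap, set_size, query_size, background, fold, pvalue, fdr
    background_n: int


def hypergeom_enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    background_n: int = 25000,
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment P(X >= overlap) per gene set.

    The background population size defaults to 25,000 (roughly the
    protein-coding mouse genome); fold enrichment is the observed overlap
    rate over its expectation; BH FDR is applied across sets.
    """
    q = set(query)
    if not q:
        raise ValueError("query gene set is empty")
    if background_n < len(q):
        raise ValueError("background smaller than the query")
    rows = []
    for name, genes in sets.items():
        gs = set(genes)
        if len(gs) > background_n:
            raise ValueError(f"gene set {name!r} larger than the background")
        k = len(q & gs)
        # P(X >= k) for X ~ Hypergeom(background_n, |set|, |query|)
        p = float(st.hypergeom.sf(k - 1, background_n, len(gs), len(q)))
        fold = (k / len(q)) / (len(gs) / background_n) if k else 0.0
        rows.append((name, k, len(gs), len(q), background_n, fold, min(p, 1.0)))
    table = pd.DataFrame(
        rows,
        columns=[
            "set",
            "overlap",
            "set_size",
            "query_size",
            "background",
            "fold_enrichment",
            "pvalue",
        ],
    ).set_index("set")
    table["fdr"] = bh_fdr(table["pvalue"].to_numpy())
    return EnrichmentResult(table, background_n)
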