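"""Synthetic bulk time-course and single-cell count generators.

Both generators emulate the statistical structure the analysis assumes —
an ordered monocyte -> Ly6C-high -> Ly6C-low macrophage time course with
trajectory archetypes for the bulk stage, and discrete cell subtypes with
exclusive markers, planted regulons, library-size variation and QC-rule
violators for the single-cell stage — and return ground-truth objects so
every downstream stage can be tested against planted labels.

Counts are negative binomial with variance ``mean + dispersion * mean**2``
(dispersion 0.1 for bulk, 0.5 for single cell, the typical over-dispersion
scales of the two assay types); ``dispersion=0`` gives the Poisson limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import DEFAULT_POPULATION_ORDER, CellMatrix, CountMatrix

# ---------------------------------------------------------------------------
# Bulk time course
# ---------------------------------------------------------------------------

#: Fixed trajectory archetype centroids (log2-fold offsets over the 5 ordered
#: populations).  Two steady shapes mirror the monotone repair/monocyte
#: programs; the rest are transient or step-like, as seen in injury time
#: courses.  Shipped as constants so recovery tests are stable.
ARCHETYPE_CENTROIDS: dict[str, tuple[float, ...]] = {
    "monotone_up": (-2.0, -1.0, 0.0, 1.0, 2.0),
    "monotone_down": (2.0, 1.0, 0.0, -1.0, -2.0),
    "transient_up_early": (-1.5, 2.0, 0.5, -0.5, -0.5),
    "transient_up_mid": (-1.5, 0.0, 2.0, 0.5, -1.0),
    "transient_down_mid": (1.5, 0.0, -2.0, -0.5, 1.0),
    "early_step_up": (-2.0, 0.8, 1.0, 1.1, 1.2),
    "late_step_down": (0.6, 0.6, 0.5, 0.4, -2.0),
}

#: Genes whose trajectories copy the monotone_up centroid; stand-ins for the
#: benchmark growth-factor genes of the repair program.
REFERENCE_GENES = ("Igf1", "Gdf15")


@dataclass
class BulkTruth:
    """Ground truth for a synthetic bulk time course."""

    archetype: pd.Series  # per-gene archetype label
    baseline: pd.Series  # per-gene baseline mean counts
    dispersion: float
    centroids: pd.DataFrame  # archetype x ordered population, log2-fold units
    reference_genes: tuple[str, ...] = REFERENCE_GENES

    def z_centroids(self) -> pd.DataFrame:
        """Centroids z-scaled per row (the representation clustering sees)."""
        c = self.centroids
        return c.sub(c.mean(axis=1), axis=0).div(c.std(axis=1, ddof=0), axis=0)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-9)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def generate_bulk(
    n_genes_per_archetype: int = 100,
    n_replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    dispersion: float = 0.1,
    exact: bool = False,
    population_order=DEFAULT_POPULATION_ORDER,
) -> tuple[CountMatrix, BulkTruth]:
    """Simulate a 5-population bulk time course with planted archetypes.

    Per gene, the mean trajectory is ``baseline * 2**(centroid + jitter)``
    with gene-wise Gaussian jitter of sd ``noise_sd`` (log2 units) applied
    independently at each population; counts are negative binomial around
    that mean.  ``exact=True`` returns the expected counts themselves
    (the deterministic noise-free limit).

    Returns the count matrix and a :class:`BulkTruth` with per-gene labels.
    """
    if n_genes_per_archetype < 2:
        raise ValueError("n_genes_per_archetype must be >= 2 (clustering undefined)")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    pops = list(population_order)
    centroids = pd.DataFrame(
        ARCHETYPE_CENTROIDS, index=pops
    ).T  # archetype x population
    if centroids.shape[1] != len(pops):
        raise ValueError("population order length does not match centroid length")

    gene_ids: list[str] = []
    labels: list[str] = []
    rows = []
    baselines = []
    sample_ids = [f"{p}_r{r + 1}" for p in pops for r in range(n_replicates)]
    pop_of_sample = [p for p in pops for _ in range(n_replicates)]

    for arch, centroid in centroids.iterrows():
        for i in range(n_genes_per_archetype):
            if arch == "monotone_up" and i < len(REFERENCE_GENES):
                gid = REFERENCE_GENES[i]
            else:
                gid = f"{arch}_g{i + 1:03d}"
            gene_ids.append(gid)
            labels.append(str(arch))
            baseline = float(2.0 ** rng.uniform(4.0, 10.0))
            baselines.append(baseline)
            jitter = rng.normal(0.0, noise_sd, size=len(pops)) if noise_sd > 0 else 0.0
            mean_per_pop = baseline * 2.0 ** (centroid.to_numpy() + jitter)
            mean_per_sample = np.repeat(mean_per_pop, n_replicates)
            if exact:
                rows.append(mean_per_sample)
            else:
                rows.append(_nb_sample(rng, mean_per_sample, dispersion).astype(float))

    counts = pd.DataFrame(np.asarray(rows), index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "population": pop_of_sample,
            "time": [pops.index(p) for p in pop_of_sample],
            "replicate": [s.rsplit("_r", 1)[1] for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    gene_meta = pd.DataFrame(
        {"gene_type": "protein_coding", "archetype": labels},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    cm = CountMatrix(counts, meta, pops, gene_meta)
    truth = BulkTruth(
        archetype=pd.Series(labels, index=gene_ids, name="archetype"),
        baseline=pd.Series(baselines, index=gene_ids, name="baseline"),
        dispersion=dispersion,
        centroids=centroids,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# Single cell
# ---------------------------------------------------------------------------

CELL_TYPES = (
    "mac_resolution",
    "mac_gfem",
    "mac_inflam",
    "mac_antigen",
    "tcell",
    "neutrophil",
)
MACROPHAGE_TYPES = CELL_TYPES[:4]

MITO_GENES = (
    "mt-Nd1",
    "mt-Nd2",
    "mt-Co1",
    "mt-Co2",
    "mt-Co3",
    "mt-Atp6",
    "mt-Atp8",
    "mt-Cytb",
    "mt-Nd4",
    "mt-Nd5",
)

#: planted regulons: TF -> (active subtype, number of targets)
REGULON_PLAN = {"Rxra": ("mac_gfem", 15), "Irf9": ("mac_inflam", 15)}

QC_RULES = ("low_genes", "low_umis", "high_mito", "high_umis")

_N_MARKERS = 8
_MARKER_FOLD = 10.0
_REGULON_FOLD = 8.0
_PROGRAM_SD = 1.0  # per-type log2 modulation of a random third of background genes
_TARGET_UMIS = 6000.0
_LIB_SD = 0.25  # lognormal sd of the per-cell library factor


@dataclass
class ScTruth:
    """Ground truth for a synthetic single-cell experiment."""

    cell_type: pd.Series  # per-barcode subtype label
    markers: dict[str, list[str]]  # subtype -> exclusive marker genes
    regulons: dict[str, list[str]]  # TF -> target gene list
    regulon_active_type: dict[str, str]  # TF -> subtype it is active in
    lib_factor: pd.Series  # per-barcode library-size factor
    mito_genes: tuple[str, ...] = MITO_GENES
    qc_violations: dict[str, str] = field(default_factory=dict)  # barcode -> rule


def generate_sc(
    n_cells_per_type: int = 60,
    n_genes: int = 400,
    qc_violation_rates: dict[str, float] | None = None,
    seed: int = 0,
    dispersion: float = 0.5,
) -> tuple[CellMatrix, ScTruth]:
    """Simulate single-cell counts with planted subtypes, markers and regulons.

    Six cell types (four macrophage-like plus two non-macrophage) each carry
    eight exclusive marker genes at :data:`_MARKER_FOLD`-fold elevation and a
    private log2-normal modulation of a quarter of the background genes, so
    types separate in PC space the way real subtypes do.  Two regulons
    (TF + 15 targets) are co-elevated only in their designated subtype.
    ``qc_violation_rates`` plants cells violating one QC rule each
    (``low_genes``, ``low_umis``, ``high_mito``, ``high_umis``); the
    fractions must sum to at most 0.5 so a clean majority remains.
    """
    if n_cells_per_type < 20:
        raise ValueError("n_cells_per_type must be >= 20")
    rates = dict.fromkeys(QC_RULES, 0.0) | (qc_violation_rates or {})
    unknown = set(rates) - set(QC_RULES)
    if unknown:
        raise ValueError(f"unknown QC rules {sorted(unknown)}")
    if sum(rates.values()) > 0.5:
        raise ValueError("QC violation fractions sum above 0.5; no clean majority")

    rng = np.random.default_rng(seed)

    # --- gene universe -----------------------------------------------------
    markers = {t: [f"{t}_mk{i + 1}" for i in range(_N_MARKERS)] for t in CELL_TYPES}
    regulons = {
        tf: [f"{tf}_tg{i + 1:02d}" for i in range(n_tg)]
        for tf, (_, n_tg) in REGULON_PLAN.items()
    }
    regulon_active = {tf: t for tf, (t, _) in REGULON_PLAN.items()}
    special = (
        [g for ms in markers.values() for g in ms]
        + list(REGULON_PLAN)
        + [g for ts in regulons.values() for g in ts]
        + list(MITO_GENES)
    )
    n_background = n_genes - len(special)
    if n_background < 50:
        raise ValueError(f"n_genes={n_genes} too small; need >= {len(special) + 50}")
    background = [f"gene{i + 1:04d}" for i in range(n_background)]
    gene_ids = special + background
    gi = {g: i for i, g in enumerate(gene_ids)}

    # --- per-type mean profiles (relative expression) ----------------------
    base = 2.0 ** rng.normal(0.0, 1.0, size=len(gene_ids))
    base[[gi[g] for g in MITO_GENES]] = 2.0 ** rng.normal(-0.4, 0.2, size=len(MITO_GENES))
    profiles = {}
    for t in CELL_TYPES:
        prof = base.copy()
        mod_idx = rng.choice(
            [gi[g] for g in background], size=max(1, n_background // 3), replace=False
        )
        prof[mod_idx] *= 2.0 ** rng.normal(0.0, _PROGRAM_SD, size=mod_idx.size)
        for other, ms in markers.items():
            idx = [gi[g] for g in ms]
            # exclusive markers: strong in their own type, near-silent elsewhere
            prof[idx] = prof[idx] * _MARKER_FOLD if other == t else prof[idx] / 50.0
        for tf, targets in regulons.items():
            idx = [gi[tf], *(gi[g] for g in targets)]
            if regulon_active[tf] == t:
                prof[idx] = prof[idx] * _REGULON_FOLD
            else:
                prof[idx] = prof[idx] / 4.0
        profiles[t] = prof / prof.sum()

    # --- cells -------------------------------------------------------------
    cell_types: list[str] = []
    barcodes: list[str] = []
    for t in CELL_TYPES:
        for i in range(n_cells_per_type):
            cell_types.append(t)
            barcodes.append(f"{t}-{i + 1:04d}")
    n_cells = len(barcodes)
    order = rng.permutation(n_cells)
    barcodes = [barcodes[i] for i in order]
    cell_types = [cell_types[i] for i in order]

    lib = np.exp(rng.normal(0.0, _LIB_SD, size=n_cells))
    cols = np.empty((n_cells, len(gene_ids)))
    for j, (bc, t) in enumerate(zip(barcodes, cell_types)):
        mean = profiles[t] * _TARGET_UMIS * lib[j]
        cols[j] = _nb_sample(rng, mean, dispersion)

    # --- planted QC violators ----------------------------------------------
    violations: dict[str, str] = {}
    n_violate = {r: int(round(rates[r] * n_cells)) for r in QC_RULES}
    pool = list(rng.permutation(n_cells))
    mito_idx = np.array([gi[g] for g in MITO_GENES])
    for rule in QC_RULES:
        for _ in range(n_violate[rule]):
            j = pool.pop()
            bc = barcodes[j]
            col = cols[j]
            if rule == "low_genes":
                # 150 expressed genes (<200), healthy UMI total, ordinary mito
                keep = rng.choice(len(gene_ids), size=150, replace=False)
                keep = keep[~np.isin(keep, mito_idx)][:140]
                new = np.zeros(len(gene_ids))
                new[keep] = rng.multinomial(3000, np.full(keep.size, 1.0 / keep.size))
                new[mito_idx[0]] = 60  # ~2% mito keeps the other rules quiet
                cols[j] = new
            elif rule == "low_umis":
                # ~700 UMIs but >=240 genes detected, so only the UMI rule fires
                detect = rng.choice(len(gene_ids), size=240, replace=False)
                new = np.zeros(len(gene_ids))
                new[detect] = 1
                extra = rng.multinomial(460, col / max(col.sum(), 1))
                new += extra
                new[mito_idx] = 0
                new[mito_idx[0]] = int(0.02 * new.sum())
                cols[j] = new
            elif rule == "high_mito":
                total = col.sum()
                col[mito_idx] = 0
                boost = rng.multinomial(int(0.15 * total), np.full(len(mito_idx), 0.1))
                col[mito_idx] = boost
            elif rule == "high_umis":
                cols[j] = _nb_sample(rng, profiles[cell_types[j]] * 40000.0, dispersion)
            violations[bc] = rule

    X = sp.csr_matrix(cols.T)
    cm = CellMatrix(X, gene_ids, barcodes)
    truth = ScTruth(
        cell_type=pd.Series(cell_types, index=barcodes, name="cell_type"),
        markers=markers,
        regulons=regulons,
        regulon_active_type=regulon_active,
        lib_factor=pd.Series(lib, index=barcodes, name="lib_factor"),
        qc_violations=violations,
    )
    return cm, truth
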