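"""Trajectory similarity screen against a benchmark gene.

Ranks every gene by the Pearson correlation of its z-scaled trajectory
with a reference gene's trajectory (the screen used to find genes that
track the repair growth factor Igf1 across the time course), and applies
the screen cutoff (similarity >= 0.9) and the stricter labeling cutoffs
(similarity > 0.93 and log2 CPM > 7.5 in the repair population).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bulk import NormalizedMatrix, TrajectoryMatrix


class ConstantTrajectoryError(ValueError):
    """A trajectory has zero variance; Pearson similarity is undefined."""


def pearson_similarity(a, b) -> float:
    """Pearson product-moment correlation of two equal-length trajectories.

    Raises :class:`ConstantTrajectoryError` for constant input; callers
    drop such genes with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("trajectories must have equal length >= 3")
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0 or nb == 0:
        raise ConstantTrajectoryError("constant trajectory: similarity undefined")
    return float(np.dot(ac, bc) / (na * nb))


@dataclass
class SimilarityTable:
    """Per-gene similarity to the reference trajectory plus pass flags."""

    table: pd.DataFrame  # similarity, max_log2cpm, label_log2cpm, pass_screen, pass_label
    reference_gene: str
    label_population: str

    @property
    def screened(self) -> pd.Index:
        return self.table.index[self.table["pass_screen"]]

    @property
    def labeled(self) -> pd.Index:
        return self.table.index[self.table["pass_label"]]


def screen_by_reference(
    tm: TrajectoryMatrix,
    nm: NormalizedMatrix,
    reference_gene: str,
    similarity_min: float = 0.9,
    label_similarity: float = 0.93,
    label_log2cpm: float = 7.5,
    label_population: str | None = None,
) -> SimilarityTable:
    """Similarity of every trajectory to ``reference_gene``'s z row.

    ``pass_screen``: similarity >= ``similarity_min``.  ``pass_label``
    additionally requires similarity > ``label_similarity`` and mean
    log2(CPM+1) above ``label_log2cpm`` in ``label_population`` (default:
    the last ordered population, the day-4 repair state).  Output is
    sorted by descending similarity, ties broken alphabetically.
    """
    if reference_gene not in tm.Z.index:
        raise KeyError(f"reference gene {reference_gene!r} absent from trajectories")
    label_population = label_population or tm.population_order[-1]
    if label_population not in tm.population_order:
        raise KeyError(f"unknown population {label_population!r}")

    Z = tm.Z.to_numpy()
    ref = tm.Z.loc[reference_gene].to_numpy()
    refc = ref - ref.mean()
    nref = np.linalg.norm(refc)
    if nref == 0:
        raise ConstantTrajectoryError(f"reference gene {reference_gene!r} is constant")
    Zc = Z - Z.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Zc, axis=1)
    sim = (Zc @ refc) / (np.where(norms == 0, np.nan, norms) * nref)

    pop_means = nm.population_mean_log2cpm().loc[tm.Z.index]
    table = pd.DataFrame(
        {
            "similarity": sim,
            "max_log2cpm": pop_means.max(axis=1),
            "label_log2cpm": pop_means[label_population],
        },
        index=tm.Z.index,
    )
    table["pass_screen"] = table["similarity"] >= similarity_min
    table["pass_label"] = (
        (table["similarity"] > label_similarity)
        & (table["label_log2cpm"] > label_log2cpm)
    )
    # similarity descending, gene id alphabetical on ties
    table = table.iloc[
        np.lexsort((table.index.to_numpy(), -table["similarity"].to_numpy()))
    ]
    return SimilarityTable(table, reference_gene, label_population)
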