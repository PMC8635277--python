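import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings as _hyp_settings

import rppkit as rk

_hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
_hyp_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bulk_noisy():
    """Moderate-noise 7-archetype time course (30 genes per archetype)."""
    cm, truth = rk.generate_bulk(30, 3, 0.2, seed=11)
    nm = rk.normalize_and_filter(cm)
    tm = rk.build_trajectories(nm)
    return cm, truth, nm, tm


@pytest.fixture(scope="session")
def bulk_exact():
    """Noise-free deterministic time course (expected counts, no sampling)."""
    cm, truth = rk.generate_bulk(20, 3, 0.0, seed=12, exact=True)
    nm = rk.normalize_and_filter(cm)
    tm = rk.build_trajectories(nm)
    return cm, truth, nm, tm


@pytest.fixture(scope="session")
def sc_clean():
    """Six planted cell types, no QC violators, post-QC and scaled."""
    cells, truth = rk.generate_sc(60, 400, None, seed=7)
    qc = rk.qc_filter(cells)
    sm = rk.normalize_scale(qc.cells)
    return cells, truth, qc, sm


def make_cell_matrix(dense, gene_ids=None, barcodes=None):
    dense = np.asarray(dense)
    gene_ids = gene_ids or [f"g{i}" for i in range(dense.shape[0])]
    barcodes = barcodes or [f"c{j}" for j in range(dense.shape[1])]
    return rk.CellMatrix(sp.csr_matrix(dense), gene_ids, barcodes)


def make_normalized(counts: pd.DataFrame, populations: list[str], order=None, cpm_min=0.0):
    """NormalizedMatrix from a raw count frame with one sample per column."""
    order = order or list(dict.fromkeys(populations))
    meta = pd.DataFrame({"population": populations}, index=counts.columns)
    cm = rk.CountMatrix(counts, meta, order)
    return rk.normalize_and_filter(cm, cpm_min=cpm_min)
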