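import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tcellfate import CellTable, CohortSpec, generate_cohort, qc_filter
from tcellfate.dataio import attach_lognorm


def make_table(values, genes, cell_ids=None, counts=None, **obs_cols):
    """CellTable from a dense matrix used directly as the lognorm layer.

    ``counts`` defaults to the same matrix (tests that only touch the
    lognorm layer do not care about raw counts).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if cell_ids is None:
        cell_ids = [f"c{i:03d}" for i in range(n)]
    obs = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    obs["sample_id"] = obs_cols.pop("sample_id", "s1")
    for k, v in obs_cols.items():
        obs[k] = v
    adata = ad.AnnData(
        X=sp.csr_matrix(values), obs=obs, var=pd.DataFrame(index=pd.Index(genes))
    )
    adata.layers["counts"] = sp.csr_matrix(
        values if counts is None else np.asarray(counts, dtype=float)
    )
    adata.layers["lognorm"] = values.copy()
    return CellTable(adata)


def counts_table(counts, genes, cell_ids=None, **obs_cols):
    """CellTable from raw counts with a properly derived lognorm layer."""
    counts = np.asarray(counts, dtype=float)
    table = make_table(counts, genes, cell_ids=cell_ids, counts=counts, **obs_cols)
    attach_lognorm(table.adata)
    return table


@pytest.fixture(scope="session")
def cohort():
    """Shared mid-size generated cohort (2 patients x 4 timepoints)."""
    spec = CohortSpec(n_patients=2, cells_per_sample=250, seed=7)
    cells, clones, truth = generate_cohort(spec)
    return spec, cells, clones, truth


@pytest.fixture(scope="session")
def qc_cohort(cohort):
    spec, cells, clones, truth = cohort
    filtered = qc_filter(cells)
    from tcellfate import ClonotypeTable

    kept = clones.df["cell_id"].isin(filtered.cell_ids)
    return spec, filtered, ClonotypeTable(clones.df[kept].reset_index(drop=True)), truth
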