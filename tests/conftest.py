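import numpy as np
import pandas as pd
import pytest
import anndata as ad

from braincomm import preprocess, simulate
from braincomm.resources import LRPair


def make_adata(counts: np.ndarray, mt_flags=None, **obs_cols) -> ad.AnnData:
    """Tiny AnnData (cells x genes) with optional mito flags and obs columns."""
    counts = np.asarray(counts, dtype=float)
    n_cells, n_genes = counts.shape
    var = pd.DataFrame(index=[f"g{i}" for i in range(n_genes)])
    var["mt"] = list(mt_flags) if mt_flags is not None else [False] * n_genes
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n_cells)])
    for k, v in obs_cols.items():
        obs[k] = list(v)
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.uns["normalized"] = False
    return adata


@pytest.fixture(scope="session")
def two_sample_adata():
    """One AD and one normal sample at the generator's defaults."""
    cfg = simulate.SimConfig(seed=1)
    return simulate.simulate_sc(
        cfg,
        [{"sample": "S1", "disease": "AD"}, {"sample": "S2", "disease": "normal"}],
    )


@pytest.fixture(scope="session")
def annotated_adata(two_sample_adata):
    """Filtered, normalized, ground-truth annotated copy."""
    adata = preprocess.filter_cells(two_sample_adata)
    adata = preprocess.normalize_log(adata)
    adata.obs["cell_type"] = adata.obs["true_cell_type"]
    return adata


@pytest.fixture(scope="session")
def background_pairs():
    return [LRPair((f"G{2 * i + 1:04d}",), (f"G{2 * i + 2:04d}",)) for i in range(15)]
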