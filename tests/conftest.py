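"""Shared fixtures: one small simulated dataset reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from scdyn.config import QcThresholds, SimulationConfig
from scdyn.preprocess import normalize_log_cpm, qc_filter_cells
from scdyn.synthdata import simulate_dataset


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(
        n_donors=30, n_genes=60, cells_per_donor_day=25, seed=42
    )


@pytest.fixture(scope="session")
def dataset(sim_config):
    return simulate_dataset(sim_config)


@pytest.fixture(scope="session")
def processed(dataset):
    """QC'd log2(CPM+1) matrix and metadata for the shared dataset."""
    adata = dataset.adata
    kept = qc_filter_cells(adata, QcThresholds.synthetic_defaults())
    post = adata[kept]
    logcpm = pd.DataFrame(
        normalize_log_cpm(np.asarray(post.X)),
        index=post.obs_names,
        columns=post.var_names,
    )
    endo = post.var_names[~post.var["is_mt"].astype(bool)]
    return {"logcpm": logcpm[endo], "meta": post.obs.copy()}
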