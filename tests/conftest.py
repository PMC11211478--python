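import numpy as np
import pandas as pd
import pytest

from dtcsig.io import CountMatrix, SampleSheet
from dtcsig.simulate import (BulkSimConfig, ClusterSpec, ScSimConfig,
                             TrackSimConfig, simulate_bulk_models, simulate_sc,
                             simulate_tracks)


@pytest.fixture(scope="session")
def small_bulk():
    """One model, 300 genes, planted 10 up / 10 down, no dropout."""
    cfg = BulkSimConfig(n_models=1, genes_total=300, n_up_planted=10,
                        n_down_planted=10, dropout_models_per_gene=0,
                        library_size_mean=300_000.0, seed=42)
    matrices, sheet, truth = simulate_bulk_models(cfg)
    return matrices[0], sheet, truth


@pytest.fixture(scope="session")
def sc_data():
    """Four-cluster UMI matrix with distinct marker programs."""
    spec = [
        ClusterSpec("CT_cycling", 60, ["MKI67", "CCNB1"], 8.0, "control"),
        ClusterSpec("osi_AT1", 60, ["AGER", "PDPN", "HOPX"], 8.0, "DTC"),
        ClusterSpec("osi_mes", 60, ["SERPINE1", "VIM"], 8.0, "DTC"),
        ClusterSpec("osi_mucous", 60, ["BPIFB1", "MUC5B"], 8.0, "DTC"),
    ]
    cfg = ScSimConfig(cluster_spec=spec, genes_total=400,
                      umi_per_cell_mean=2000, seed=7)
    return simulate_sc(cfg)


@pytest.fixture(scope="session")
def noiseless_tracks():
    cfg = TrackSimConfig(n_cells_per_condition=60, fate_probs=(0.4, 0.3, 0.3),
                         channel_noise_sd=0.0, seed=3)
    return simulate_tracks(cfg)


@pytest.fixture()
def tiny_counts():
    """3 genes x 4 samples with an obvious two-group structure."""
    counts = np.array([[10, 12, 40, 44], [100, 90, 95, 105], [5, 7, 6, 4]])
    cm = CountMatrix(["GA", "GB", "GC"], ["c1", "c2", "t1", "t2"], counts)
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": ["c1", "c2", "t1", "t2"],
        "model_id": "m1",
        "condition": ["control", "control", "DTC", "DTC"],
    }))
    return cm, sheet
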