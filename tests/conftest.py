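import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

import tmescope as tm

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def tiny_counts() -> tm.CountMatrix:
    """3 genes x 4 cells with hand-checkable entries and two patients."""
    genes = ["EPCAM", "COL1A1", "MT-CO1"]
    cells = ["c1", "c2", "c3", "c4"]
    dense = np.array(
        [
            [5, 0, 2, 1],
            [0, 3, 1, 0],
            [1, 1, 0, 2],
        ]
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s2", "s2"],
            "patient_id": ["P1", "P1", "P2", "P2"],
            "tissue": ["primary", "primary", "metastasis", "metastasis"],
        },
        index=pd.Index(cells, name="barcode"),
    )
    return tm.CountMatrix(genes, cells, sp.csr_matrix(dense), meta)


@pytest.fixture(scope="session")
def sc_sim():
    """A moderate planted simulation shared by the single-cell unit tests."""
    cfg = tm.ScSimConfig(
        n_patients=2,
        cells_per_patient=400,
        n_genes=800,
        n_markers_per_type=10,
        marker_fold=8.0,
        base_mean=1.5,
        seed=11,
    )
    cm, truth = tm.simulate_sc(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def sc_pipeline(sc_sim):
    """QC -> normalize -> embed -> cluster -> annotate on the shared sim."""
    _, cm, truth = sc_sim
    filtered, _ = tm.qc_filter(cm, tm.QcThresholds(min_umi=500, min_shannon=3.0))
    nm = tm.log_normalize(filtered)
    emb = tm.embed(nm, n_hvg=500, n_pcs=20, k_neighbors=15, seed=11)
    # resolution 1.2: tumor cells split per patient on this small fixture
    clusters = tm.cluster(emb, resolution=1.2, seed=11)
    panel = {t: tm.GeneSet(t, g) for t, g in truth.markers.items()}
    ann = tm.assign_labels(clusters, nm, panel, seed=11)
    return {
        "counts": filtered,
        "truth": truth,
        "nm": nm,
        "embedding": emb,
        "clusters": clusters,
        "panel": panel,
        "ann": ann,
    }


@pytest.fixture(scope="session")
def bulk_sim():
    cfg = tm.BulkSimConfig(n_patients=120, n_genes=60, beta=np.log(2.0), seed=5)
    cohort, truth = tm.simulate_bulk(cfg)
    return cfg, cohort, truth
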