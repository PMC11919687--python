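import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from trtkit import SimConfig, simulate_cohort
from trtkit.io import CellMatrix, normalize_log

from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_cell_matrix(counts, patients=None, clones=None, lognorm=True):
    """Build a small CellMatrix from a dense genes x cells array."""
    counts = np.asarray(counts)
    g, c = counts.shape
    genes = [f"g{i}" for i in range(g)]
    barcodes = [f"bc{i}" for i in range(c)]
    meta = pd.DataFrame(
        {
            "patient": patients if patients is not None else ["P1"] * c,
            "clone_id": clones if clones is not None else [f"cl{i}" for i in range(c)],
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    cm = CellMatrix(
        gene_ids=genes, cell_barcodes=barcodes, counts=sp.csr_matrix(counts), cell_meta=meta
    )
    return normalize_log(cm) if lognorm else cm


@pytest.fixture(scope="session")
def small_cohort():
    """6-patient cohort with a clear planted signal, for fast CV tests."""
    cfg = SimConfig(
        n_patients=6,
        clones_per_patient=14,
        n_genes=300,
        n_signal_genes_up=25,
        n_signal_genes_down=12,
        effect_size=1.5,
        seed=11,
    )
    cm, ct, truth = simulate_cohort(cfg)
    return normalize_log(cm), ct, truth


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong-effect cohort for parameter-recovery checks."""
    cfg = SimConfig(
        n_patients=6,
        clones_per_patient=14,
        n_genes=300,
        n_signal_genes_up=25,
        n_signal_genes_down=12,
        effect_size=2.5,
        seed=5,
    )
    cm, ct, truth = simulate_cohort(cfg)
    return normalize_log(cm), ct, truth
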