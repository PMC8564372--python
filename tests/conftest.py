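import numpy as np
import pandas as pd
import pytest

import rarobust as rr


@pytest.fixture(scope="session")
def small_noise_free():
    """Noise-free dataset: 12 clutches, 300 genes, deterministic."""
    cfg = rr.SimulationConfig(seed=11, n_genes=300, noise_sd=0.0, ct_jitter_sd=0.0)
    matrix, ct, truth = rr.simulate_dataset(cfg)
    return cfg, matrix, ct, truth


@pytest.fixture(scope="session")
def small_noisy():
    """Default-noise dataset at reduced gene count."""
    cfg = rr.SimulationConfig(seed=7, n_genes=300)
    matrix, ct, truth = rr.simulate_dataset(cfg)
    return cfg, matrix, ct, truth


def make_matrix(values, meta_rows, scale="log2"):
    """Assemble an ExpressionMatrix from plain nested data."""
    frame = pd.DataFrame(values)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return rr.ExpressionMatrix(frame, meta, scale)


@pytest.fixture
def tiny_meta():
    """One clutch, Control + RA, four time points."""
    rows = []
    for trt in ("Control", "RA"):
        for t in (0.0, 1.5, 3.0, 4.5):
            rows.append(
                {
                    "sample_id": f"X_{trt}_{t:g}h",
                    "clutch": "X",
                    "treatment": trt,
                    "time_h": t,
                    "assay": "rnaseq",
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")
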