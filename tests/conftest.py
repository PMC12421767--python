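import numpy as np
import pandas as pd
import pytest

import saltnet as sn


@pytest.fixture
def tiny_sheet() -> sn.SampleSheet:
    """2 treatments x 2 times x 1 rep, one ecotype."""
    return sn.SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "ecotype": ["E"] * 4,
                "treatment": ["control", "control", "salt", "salt"],
                "time": ["0h", "24h", "0h", "24h"],
                "batch": ["b1"] * 4,
            }
        )
    )


@pytest.fixture(scope="session")
def small_dataset() -> sn.SimConfig:
    """Desk-scale paired dataset shared by read-only tests."""
    cfg = sn.SimConfig(
        n_genes=120,
        n_metabolites=4,
        ecotypes=("HLZY",),
        sset_fraction=0.1,
        seed=404,
    )
    return sn.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def full_design_dataset() -> sn.SimConfig:
    """Two-ecotype factorial used by clustering / multivariate tests."""
    cfg = sn.SimConfig(n_genes=60, n_metabolites=6, sset_fraction=0.2, seed=77)
    return sn.simulate_dataset(cfg)


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Independent Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
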