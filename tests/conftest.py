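import numpy as np
import pandas as pd
import pytest

from omicmr.simulate import selection_fixture


@pytest.fixture(scope="session")
def selection_region():
    """Designed region where each selection stage removes exactly one SNP."""
    return selection_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_instruments(bx, by, se_x=0.01, se_y=0.02, eaf=0.3):
    """Instrument table from parallel effect arrays (helper, not a fixture)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    k = len(bx)
    return pd.DataFrame({
        "snp_id": [f"iv{i}" for i in range(k)],
        "beta_exp": bx,
        "se_exp": np.broadcast_to(se_x, k).astype(float),
        "beta_out": by,
        "se_out": np.broadcast_to(se_y, k).astype(float),
        "eaf_exp": np.broadcast_to(eaf, k).astype(float),
        "eaf_out": np.broadcast_to(eaf, k).astype(float),
        "pval_exp": 1e-20,
        "f_stat": (bx / np.broadcast_to(se_x, k)) ** 2,
        "flags": "",
    })
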