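import numpy as np
import pandas as pd
import pytest

from paleotrait.synthetic_data import SimConfig, simulate_dataset
from paleotrait.traits import filter_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset reused across read-only tests."""
    return simulate_dataset(SimConfig(n_samples_per_period=(24, 10, 10), n_motus=50, seed=42))


@pytest.fixture(scope="session")
def filtered(small_dataset):
    rm, tt, _ = filter_dataset(small_dataset.read_matrix, small_dataset.traits)
    st = small_dataset.samples
    st = st[st["sample_id"].isin(rm.index)].reset_index(drop=True)
    periods = st.set_index("sample_id")["period"].loc[rm.index]
    return rm, tt, st, periods


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_trait_table(overrides: dict | None = None) -> pd.DataFrame:
    """Three fully defined MOTUs; ``overrides`` patches (motu, column) cells."""
    tt = pd.DataFrame(
        {
            "growth_form": ["forb", "graminoid", "tree_shrub"],
            "myc_type": ["AM", "NM", "ECM"],
            "myc_status": ["FM", "NM", "OM"],
            "n_fix": ["fixer", "nonfixer", "nonfixer"],
            "pollination": ["insect", "wind", "wind"],
        },
        index=pd.Index(["m1", "m2", "m3"], name="motu_id"),
    )
    for (motu, col), val in (overrides or {}).items():
        tt.loc[motu, col] = val
    return tt
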