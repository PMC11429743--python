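import numpy as np
import pandas as pd
import pytest

from gxepred import SimConfig, arc_cosine_kernel, simulate_bundle


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_hybrids=60, n_markers=120, n_locations=6, n_years=2, n_states=3, seed=11
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


@pytest.fixture(scope="session")
def small_kernel(small_bundle):
    return arc_cosine_kernel(small_bundle.geno)


@pytest.fixture(scope="session")
def artifact_bundle():
    """~10,000 plots with known injected artifact rates."""
    cfg = SimConfig(
        n_hybrids=200,
        n_markers=60,
        n_locations=25,
        n_years=1,
        n_states=5,
        frac_hybrids_per_env=0.5,
        outlier_rate=0.01,
        low_stand_rate=0.02,
        disease_trial_rate=0.0,
        seed=29,
    )
    return simulate_bundle(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_qc_table():
    """One environment, 12 records: one 3-SD outlier, one low stand count.

    Hand enumeration: the full-table environment mean is 10.833 and the
    sample SD 3.035, so only the 20.0 record exceeds 3 SD (z = 3.02);
    every other record is below z = 0.9.
    """
    yields = [8.2, 9.1, 9.8, 10.4, 11.0, 9.5, 10.9, 10.1, 9.0, 11.4, 10.6, 20.0]
    stands = [60, 60, 19, 60, 60, 60, 60, 60, 60, 60, 60, 60]
    return pd.DataFrame(
        {
            "env_id": "E1_2020",
            "hybrid": [f"H{i:02d}" for i in range(12)],
            "yield_mg_ha": yields,
            "stand_count": stands,
            "replicate": 1,
            "block": 1,
            "treatment": "Standard",
        }
    )
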