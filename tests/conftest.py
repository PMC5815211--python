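import numpy as np
import pandas as pd
import pytest

from admp import simdata
from admp.ioformats import BetaMatrix, site_index


@pytest.fixture
def rng():
    return np.random.default_rng(20240216)


@pytest.fixture
def small_config():
    return simdata.SimConfig(
        n_sites=60,
        n_samples=24,
        age_range_weeks=(10.0, 150.0),
        frac_admps=0.25,
        gradient_scale=0.003,
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture
def noisy_config(small_config):
    from dataclasses import replace

    return replace(small_config, noise_sd=0.02, n_samples=40)


def beta_from_arrays(values: np.ndarray, ages: np.ndarray, chrom="chr1") -> BetaMatrix:
    """Hand-build a BetaMatrix from a sites x samples array and ages."""
    n_sites, n_samples = values.shape
    idx = site_index([chrom] * n_sites, np.arange(n_sites) * 1000 + 500)
    ids = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {"age_weeks": ages, "species": "toy", "group": "all"},
        index=pd.Index(ids, name="sample_id"),
    )
    return BetaMatrix(pd.DataFrame(values, index=idx, columns=ids), meta)
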