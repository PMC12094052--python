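import numpy as np
import pytest

from rumiclust.dtw import BehaviorSeries
from rumiclust.simulate import GroupSpec, SimConfig, simulate_herd


def make_series(cow_id: str, values) -> BehaviorSeries:
    """BehaviorSeries from an (n, 2) array with synthetic hourly stamps."""
    values = np.asarray(values, dtype=float)
    ts = np.arange(len(values)).astype("datetime64[h]")
    return BehaviorSeries(cow_id, ts, values)


def univariate(cow_id: str, xs) -> BehaviorSeries:
    """Embed a 1-D sequence as (x, 0) pairs."""
    xs = np.asarray(xs, dtype=float)
    return make_series(cow_id, np.column_stack([xs, np.zeros_like(xs)]))


def noiseless_config(n_cows=8, n_days=2, seed=0, uniform_profiles=False):
    """Two-group herd with every noise source off."""
    cfg = SimConfig(n_cows=n_cows, n_days=n_days, seed=seed,
                    cow_sd={}, hour_noise_sd=0.0, day_noise_sd={})
    if uniform_profiles:
        for g in cfg.groups:
            g.rt_profile_weights = np.ones(24)
            g.et_profile_weights = np.ones(24)
    return cfg


@pytest.fixture(scope="session")
def small_herd():
    """Default-parameter herd reused across tests (12 cows, 4 days)."""
    cfg = SimConfig(n_cows=12, n_days=4, seed=11)
    dataset, truths = simulate_herd(cfg)
    return cfg, dataset, truths


@pytest.fixture(scope="session")
def noiseless_herd():
    cfg = noiseless_config(n_cows=8, n_days=2, seed=5)
    dataset, truths = simulate_herd(cfg)
    return cfg, dataset, truths
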