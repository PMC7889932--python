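import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from netage.config import ColonyConfig
from netage.pipeline import run_colony_pipeline

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

warnings.filterwarnings("ignore", message="dropped .* events")


@pytest.fixture(scope="session")
def default_colony():
    """The default heterogeneous-development colony (200 bees, 25 days)."""
    return run_colony_pipeline(ColonyConfig(seed=1))


@pytest.fixture(scope="session")
def homogeneous_colony():
    """Every bee transitions on the same day-of-life (no heterogeneity)."""
    cfg = ColonyConfig(cluster_probs=(1.0, 0.0, 0.0),
                       transition_day_sds=(0.0, 0.0, 0.0), seed=2)
    return run_colony_pipeline(cfg)


@pytest.fixture(scope="session")
def small_colony_config():
    return ColonyConfig(n_bees=40, n_days=8, emergence_schedule=[(-6, 20), (0, 20)],
                        frames_per_day=96, seed=11)


@pytest.fixture(scope="session")
def lifetime_colony():
    """Colony for death-date recovery: all bees emerge inside the window."""
    from netage.simulate import simulate_detection_counts, simulate_ground_truth
    cfg = ColonyConfig(n_bees=100, n_days=80,
                       emergence_schedule=[(0, 50), (5, 25), (10, 25)],
                       detection_noise=20.0, alive_count_mean=1000.0, seed=7)
    gt = simulate_ground_truth(cfg)
    counts = simulate_detection_counts(gt, cfg)
    return cfg, gt, counts


def planted_trajectories(n_per_group: int = 15, n_days: int = 30,
                         noise_sd: float = 1.0, seed: int = 5):
    """Network-age-like series for three developmental groups.

    Groups transition from low (~2) to high (~38) network age around days 8,
    20, or never, following logistic curves with small additive noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    labels = {}
    bee = 0
    for g, t0 in enumerate([8.0, 20.0, np.inf]):
        for _ in range(n_per_group):
            days = np.arange(n_days)
            if np.isinf(t0):
                base = np.full(n_days, 2.0)
            else:
                base = 2.0 + 36.0 / (1.0 + np.exp(-(days - t0) / 1.5))
            vals = base + noise_sd * rng.standard_normal(n_days)
            rows.append(pd.DataFrame({"bee_id": bee, "day": days,
                                      "network_age": vals}))
            labels[bee] = g
            bee += 1
    return pd.concat(rows, ignore_index=True), pd.Series(labels)
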