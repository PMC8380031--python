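import logging

import numpy as np
import pytest

from lwpcal import RegressionDataset, SimulationConfig, simulate_study


@pytest.fixture(autouse=True)
def _quiet_logs():
    # the uncertainty floor and pooling warnings are expected in many tests
    logging.getLogger("lwpcal").setLevel(logging.ERROR)
    yield


@pytest.fixture
def benchmark_dataset() -> RegressionDataset:
    """Classic 10-point bivariate benchmark with strongly varying weights
    in both coordinates (weights given as 1/delta^2)."""
    x = np.array([0.0, 0.9, 1.8, 2.6, 3.3, 4.4, 5.2, 6.1, 6.5, 7.4])
    y = np.array([5.9, 5.4, 4.4, 4.6, 3.5, 3.7, 2.8, 2.8, 2.4, 1.5])
    wx = np.array([1000, 1000, 500, 800, 200, 80, 60, 20, 1.8, 1.0])
    wy = np.array([1, 1.8, 4, 8, 20, 20, 70, 70, 100, 500.0])
    return RegressionDataset(x, y, 1 / np.sqrt(wx), 1 / np.sqrt(wy),
                             label="benchmark")


def random_dataset(rng: np.random.Generator, n: int | None = None,
                   m: float = 4.0, c: float = -5.0) -> RegressionDataset:
    """A well-behaved random noisy dataset in the NDVI/LWP regime."""
    if n is None:
        n = int(rng.integers(6, 15))
    x = rng.uniform(0.4, 0.9, n)
    y = m * x + c + rng.normal(0.0, 0.12, n)
    dx = rng.uniform(0.008, 0.03, n)
    dy = rng.uniform(0.04, 0.12, n)
    return RegressionDataset(x, y, dx, dy)


@pytest.fixture
def exact_line_study():
    """Noise-free simulated campaign: every fit must recover the truth."""
    cfg = SimulationConfig(sigma_lwp=0.0, sigma_ndvi=0.0, sigma_lof=0.0,
                           treatments={"D": 0.0, "F": 0.0}, seed=11)
    return simulate_study(cfg)
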