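import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrmediate import HarmonizedSet, SimulationConfig, simulate_chain

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_harmonized() -> HarmonizedSet:
    """5 SNPs, heterogeneous ratios, unequal SEs."""
    rng = np.random.default_rng(7)
    bx = np.array([0.12, 0.08, -0.15, 0.2, 0.1])
    sx = np.full(5, 0.01)
    by = np.array([0.06, 0.05, -0.06, 0.11, 0.04])
    sy = np.array([0.02, 0.03, 0.025, 0.02, 0.04]) + rng.uniform(0, 0.005, 5)
    return HarmonizedSet.from_arrays(bx, sx, by, sy)


@pytest.fixture
def homogeneous_harmonized() -> HarmonizedSet:
    """Every Wald ratio exactly 0.5 -> all methods must agree."""
    bx = np.array([0.1, 0.2, 0.4, 0.25])
    return HarmonizedSet.from_arrays(bx, np.full(4, 0.01), 0.5 * bx, np.full(4, 0.02))


@pytest.fixture(scope="session")
def default_chain():
    """One simulated chain under the default study conditions (seed 11)."""
    return simulate_chain(SimulationConfig(seed=11))


def sumstat_frame(n: int, seed: int = 0) -> pd.DataFrame:
    """Random valid canonical summary-stat frame (test helper)."""
    rng = np.random.default_rng(seed)
    pairs = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
    idx = rng.integers(0, 4, n)
    beta = rng.normal(0, 0.1, n)
    se = rng.uniform(0.01, 0.05, n)
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(n)],
            "chr": rng.integers(1, 23, n).astype(str),
            "pos": rng.integers(1, 10**8, n),
            "ea": [pairs[i][0] for i in idx],
            "oa": [pairs[i][1] for i in idx],
            "eaf": rng.uniform(0.05, 0.95, n),
            "beta": beta,
            "se": se,
            "pval": np.clip(2 * 0.5 * np.exp(-0.5 * (beta / se) ** 2), 1e-300, 1.0),
            "n": 10000,
        }
    )
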