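import numpy as np
import pandas as pd
import pytest

from che_gap.config import SimConfig
from che_gap.synthetic_data import generate_population


def make_wave(
    rng: np.random.Generator,
    n: int,
    wave: int = 2013,
    max_size: int = 6,
    zero_oop_frac: float = 0.2,
) -> pd.DataFrame:
    """Small random wave of households for oracle / property tests."""
    size = rng.integers(1, max_size + 1, size=n)
    food = rng.uniform(10, 500, size=n)
    housing = rng.uniform(0, 300, size=n)
    utilities = rng.uniform(0, 120, size=n)
    other = rng.uniform(5, 800, size=n)
    oop = np.where(rng.random(n) < zero_oop_frac, 0.0, rng.uniform(0, 600, size=n))
    return pd.DataFrame(
        {
            "household_id": wave * 100_000 + np.arange(1, n + 1),
            "wave": wave,
            "residency": rng.choice(["urban", "rural"], size=n),
            "household_size": size,
            "exp_food": food,
            "exp_housing": housing,
            "exp_utilities": utilities,
            "exp_oop_health": oop,
            "exp_other": other,
            "self_rated_unaffordable": pd.array(
                rng.integers(0, 2, size=n), dtype="Int64"
            ),
        }
    )


@pytest.fixture(scope="session")
def small_population() -> pd.DataFrame:
    """A reduced but fully structured synthetic survey (2 waves x 1500)."""
    cfg = SimConfig(n_households_per_wave=1500, waves=(2013, 2017), seed=42)
    return generate_population(cfg)


@pytest.fixture(scope="session")
def default_population() -> pd.DataFrame:
    """The full default synthetic survey (4 waves x 10 000, fixed seed)."""
    return generate_population(SimConfig(seed=20130))
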