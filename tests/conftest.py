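import numpy as np
import pandas as pd
import pytest

from spotstrat import CohortConfig, generate_cohort


def long_spot_table(per_replicate: dict[tuple[str, int], dict[str, float]]) -> pd.DataFrame:
    """Build a long spot table from {(patient, replicate): {spot: volume}}."""
    rows = [
        {"patient_id": p, "replicate_index": r, "spot_id": s, "raw_volume": v}
        for (p, r), spots in per_replicate.items()
        for s, v in spots.items()
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_spot_table():
    return long_spot_table(
        {
            ("p1", 0): {"s1": 2.0, "s2": 3.0, "s3": 5.0},
            ("p1", 1): {"s1": 2.2, "s2": 2.9, "s3": 4.9},
            ("p1", 2): {"s1": 1.9, "s2": 3.1, "s3": 5.2},
            ("p2", 0): {"s1": 4.0, "s2": 4.0, "s3": 2.0},
            ("p2", 1): {"s1": 4.1, "s2": 3.8, "s3": 2.1},
            ("p2", 2): {"s1": 3.9, "s2": 4.2, "s3": 1.8},
        }
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed 11)."""
    return generate_cohort(CohortConfig(seed=11))


def noiseless_config(**overrides) -> CohortConfig:
    base = dict(replicate_cv_range=(0.0, 0.0), dropout_rate=0.0, seed=5)
    base.update(overrides)
    return CohortConfig(**base)
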