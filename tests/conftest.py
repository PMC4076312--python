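import numpy as np
import pandas as pd
import pytest

from lateralize.bootstrap_li import TMapVolume
from lateralize.models import LH_MIXTURE, RH_MIXTURE


@pytest.fixture(scope="session")
def lh_model():
    """Published 4-component left-hander mixture."""
    return LH_MIXTURE


@pytest.fixture(scope="session")
def rh_model():
    """Published 3-component right-hander mixture."""
    return RH_MIXTURE


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def flat_volume():
    """Deterministic volume: left voxels all 2.0, right voxels all 1.0."""
    values = np.zeros((8, 6, 6))
    left = np.zeros((8, 6, 6), dtype=bool)
    right = np.zeros((8, 6, 6), dtype=bool)
    left[:4] = True
    right[4:] = True
    values[left] = 2.0
    values[right] = 1.0
    return TMapVolume(values, left, right)


@pytest.fixture()
def twenty_voxel_volume():
    """Seeded stochastic fixture with 20 suprathreshold voxels per side."""
    gen = np.random.default_rng(777)
    values = np.zeros((10, 2, 2))
    left = np.zeros((10, 2, 2), dtype=bool)
    right = np.zeros((10, 2, 2), dtype=bool)
    left[:5] = True
    right[5:] = True
    values[left] = gen.gamma(3.0, 1.0, size=20) + 0.1
    values[right] = gen.gamma(2.0, 1.0, size=20) + 0.1
    return TMapVolume(values, left, right)


def cohort_from_counts(counts: dict) -> pd.DataFrame:
    """Expand {(handedness, lat_type): n} into a subject-level table."""
    rows = []
    for (hand, lat), n in counts.items():
        rows += [{"handedness": hand, "lat_type": lat}] * n
    df = pd.DataFrame(rows)
    df["subject_id"] = [f"s{i}" for i in range(len(df))]
    return df


@pytest.fixture(scope="session")
def published_type_cohort():
    """Subject-level expansion of the published type-by-handedness counts."""
    return cohort_from_counts(
        {
            ("RH", "Typical"): 130,
            ("RH", "Ambilateral"): 14,
            ("LH", "Typical"): 120,
            ("LH", "Ambilateral"): 23,
            ("LH", "Strongly-atypical"): 10,
        }
    )
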