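import pandas as pd
import pytest

from fpmiron.recalls import build_profiles
from fpmiron.simulate import generate_cohort


@pytest.fixture()
def comp_df() -> pd.DataFrame:
    """Small hand-built composition table covering high/low mixes.

    beef: high iron, low ascorbic/phytate; orange: high ascorbic only;
    bran: high phytate and high ratio; rice: low everything.
    """
    return pd.DataFrame(
        {
            "food_id": ["beef", "orange", "bran", "rice"],
            "name": ["ground beef", "orange", "wheat bran", "white rice"],
            "iron_mg_per_100g": [2.6, 0.1, 10.6, 0.2],
            "ascorbic_mg_per_100g": [0.0, 53.0, 0.0, 0.0],
            "phytate_mg_per_100g": [0.0, 20.0, 3000.0, 40.0],
        }
    )


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic cohort (27 participants, 3 recall days)."""
    return generate_cohort(seed=42)


@pytest.fixture(scope="session")
def cohort_profiles(cohort):
    return build_profiles(cohort.recalls, cohort.composition)
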