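import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nsafarm import CropNutrientTable, generate_fixtures

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calibrated_config():
    return generate_fixtures(1, "calibrated").config


@pytest.fixture(scope="session")
def uncalibrated_config():
    return generate_fixtures(1, "uncalibrated").config


@pytest.fixture()
def single_crop_table():
    """One grain-like crop on the whole hectare, plus a beef row."""

    def make(n_content=0.02, conv_yield=5000.0, area=1.0, energy=3500.0):
        frame = pd.DataFrame(
            {
                "item": ["grain", "beef"],
                "land_share_ha": [area, 0.0],
                "conv_yield_kg_per_ha": [conv_yield, 0.0],
                "n_content_kg_per_kg": [n_content, 0.032],
                "energy_kcal_per_kg": [energy, 2500.0],
                "vitamin_b12_ug_per_kg": [0.0, 25.0],
            }
        )
        frame["protein_g_per_kg"] = 6250.0 * frame["n_content_kg_per_kg"]
        return CropNutrientTable(frame, area_vegetal=area)

    return make
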