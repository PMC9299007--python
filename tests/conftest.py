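import numpy as np
import pandas as pd
import pytest

from socpotential.synthetic_data import GeneratorConfig, generate_cells


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cells():
    """A small but fully populated synthetic cell table (seeded)."""
    return generate_cells(GeneratorConfig(n_cells=500, seed=7))


def make_record(**overrides):
    """One valid effect-size record row with overridable fields."""
    base = {
        "source_id": "s1",
        "measure": "M1",
        "intervention": "IF-NF",
        "climate": "temperate",
        "metric": "stock_annual",
        "value": 0.2,
        "variation_kind": "SE",
        "variation_value": 0.05,
        "variation_value2": np.nan,
        "n_pairs": 10,
        "depth_m": 0.3,
        "duration_yr": 20.0,
    }
    base.update(overrides)
    return base


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def records_df():
    def build(*rows):
        return pd.DataFrame([make_record(**r) for r in rows])

    return build
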