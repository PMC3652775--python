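import numpy as np
import pandas as pd
import pytest

import soahia as sa
from soahia.regions import MIDWEST_EAST, SOUTH, WEST


def make_pairs(x_by_region, y_by_region):
    """Assemble a monitor-pair table from per-region x/y lists."""
    rows = []
    i = 0
    for region in x_by_region:
        for xv, yv in zip(x_by_region[region], y_by_region[region]):
            rows.append({"site_id": f"S{i:03d}", "month": "Jan", "region": region,
                         "model_ugCm3": xv, "obs_ugCm3": yv})
            i += 1
    return pd.DataFrame(rows)


@pytest.fixture
def toy_pairs():
    """A fixed 12-observation campaign, 4 sites per region.

    Hand-constructed around the regional bias structure (steep slope in
    the Midwest/East, shallow in the West) with mild scatter, small
    enough for brute-force likelihood evaluation.
    """
    x = {MIDWEST_EAST: [0.02, 0.05, 0.08, 0.11],
         SOUTH: [0.03, 0.06, 0.09, 0.12],
         WEST: [0.02, 0.04, 0.07, 0.10]}
    y = {MIDWEST_EAST: [0.09, 0.17, 0.26, 0.35],
         SOUTH: [0.07, 0.12, 0.16, 0.21],
         WEST: [0.04, 0.06, 0.09, 0.12]}
    return make_pairs(x, y)


@pytest.fixture
def identity_pairs():
    """Observations exactly equal to model values in all three regions."""
    x = {r: [0.02, 0.05, 0.08, 0.11] for r in (MIDWEST_EAST, SOUTH, WEST)}
    return make_pairs(x, x)


@pytest.fixture
def low_noise_truth():
    """Generating truth at the published slopes with small monitor noise."""
    return sa.SyntheticTruth(obs_noise_sd=0.02, seed=42)


@pytest.fixture
def small_campaign(low_noise_truth):
    """A 300-unit field with a 300-pair monitor campaign."""
    field = sa.generate_field(low_noise_truth, 300)
    monitors = sa.generate_monitors(field, low_noise_truth, 300, 43)
    return field, monitors


@pytest.fixture
def flat_field():
    """A 6-unit field at a constant 0.2 μg/m³, half urban."""
    df = pd.DataFrame({
        "unit_id": [f"U{i:05d}" for i in range(6)],
        "state": ["NY", "NY", "TX", "TX", "CA", "CA"],
        "region": [MIDWEST_EAST, MIDWEST_EAST, SOUTH, SOUTH, WEST, WEST],
        "urban": [True, False, True, False, True, False],
        "conc_ugm3": [0.2] * 6,
    })
    return sa.ConcentrationField(df, ("simulated",))


@pytest.fixture
def flat_population():
    """Populations/rates matching flat_field units, constant rate 0.008."""
    return pd.DataFrame({
        "unit_id": [f"U{i:05d}" for i in range(6)],
        "state": ["NY", "NY", "TX", "TX", "CA", "CA"],
        "population": [1_000_000] * 6,
        "baseline_rate": [0.008] * 6,
        "urban": [True, False, True, False, True, False],
    })
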