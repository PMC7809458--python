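import math

import numpy as np
import pytest

from paleoseason.io import IsotopeSample, ToothSeries
from paleoseason.synthetic import generate, make_paper_like_scenario

TWO_PI = 2.0 * math.pi


def make_series(
    positions,
    values,
    tooth_id="T1",
    layer_id="2",
):
    samples = [
        IsotopeSample(tooth_id=tooth_id, layer_id=layer_id, position_mm=float(p), d18O=float(v))
        for p, v in zip(positions, values)
    ]
    return ToothSeries(tooth_id=tooth_id, layer_id=layer_id, samples=samples)


def sinusoid_series(A=1.0, M=0.0, lam=30.0, phi=0.0, n=15, span=45.0, x0=0.0, noise_sd=0.0, rng=None):
    x = np.linspace(x0, x0 + span, n)
    y = M + A * np.sin(TWO_PI * x / lam + phi)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        y = y + noise_sd * rng.standard_normal(n)
    return make_series(x, y)


@pytest.fixture(scope="session")
def paper_like_tables():
    """One seeded paper-like synthetic dataset shared by read-only tests."""
    scenario = make_paper_like_scenario(seed=1)
    return scenario, generate(scenario)


@pytest.fixture()
def enamel_csv(tmp_path, paper_like_tables):
    _, tables = paper_like_tables
    path = tmp_path / "enamel.csv"
    tables["enamel"].to_csv(path, index=False)
    return path
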