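import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import monofilm as mf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dppe_water():
    """Noisy DPPE-on-water preset isotherm with metadata (seed 1)."""
    spec, psi = mf.preset_spec("DPPE", "water", seed=1)
    meta = mf.preset_metadata("DPPE", "water")
    return mf.generate_isotherm(spec, psi, metadata=meta)


@pytest.fixture(scope="session")
def noiseless_lc_spec():
    """Noiseless curve with a constant-elasticity LC branch (K = 240)."""
    return mf.SyntheticIsothermSpec(
        area_max=120.0,
        area_min=18.0,
        n_points=2000,
        liftoff_area=90.0,
        volmer_coarea=70.5,
        lc_elasticity=240.0,
        collapse_pressure=58.0,
        noise_sd_pressure=0.0,
        noise_sd_potential=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_lc_iso(noiseless_lc_spec):
    return mf.generate_isotherm(noiseless_lc_spec)


@pytest.fixture()
def gas_only_iso():
    """A record that never lifts off: baseline noise only."""
    rng = np.random.default_rng(5)
    area = np.linspace(150.0, 50.0, 400)
    pressure = rng.normal(0.0, 0.05, size=area.size)
    return mf.CompressionIsotherm(area=area, pressure=pressure)
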