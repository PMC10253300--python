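"""Shared fixtures for the synbias test suite."""

import numpy as np
import pytest

from synbias import (
    HillParams,
    SimulationConfig,
    base2_doses,
    config_from_presets,
    generate_checkerboard,
)


@pytest.fixture
def simple_params():
    """A plain full-range curve with unit-scale midpoint."""
    return HillParams(emin=100.0, emax=0.0, ec50=1.0, h=1.5)


@pytest.fixture
def plateau_params():
    """A partial-effect curve plateauing at 20% viability."""
    return HillParams(emin=100.0, emax=20.0, ec50=0.05, h=1.0)


@pytest.fixture
def doses9():
    return base2_doses(16.0, 9)


@pytest.fixture
def noisefree_bliss_dataset(simple_params, plateau_params):
    """Bliss-null checkerboard with zero noise and zero offset."""
    cfg = SimulationConfig(
        row_params=simple_params,
        col_params=plateau_params,
        row_doses=base2_doses(16.0, 9),
        col_doses=base2_doses(2.0, 9),
        null_model="bliss",
        noise_sd=0.0,
        n_replicates=4,
        seed=0,
    )
    return generate_checkerboard(cfg)


@pytest.fixture
def noisy_bliss_dataset():
    """Default-preset Bliss-null checkerboard with the standard noise model."""
    return generate_checkerboard(
        config_from_presets("indomethacin_like", "gemcitabine_like", seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
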