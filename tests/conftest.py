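import numpy as np
import pytest

from helipause import (
    IonicConditions,
    MeasurementConfig,
    SimulationConfig,
    calibrate_prefactor,
    compute_bp_energies,
    generate_trace_set,
    make_hairpin,
)


@pytest.fixture(scope="session")
def hairpin():
    """Default 174-bp emulation hairpin with GC clusters at 55/90/120."""
    return make_hairpin(seed=1)


@pytest.fixture(scope="session")
def profile(hairpin):
    return compute_bp_energies(hairpin, IonicConditions())


@pytest.fixture(scope="session")
def delayed_config(hairpin, profile):
    """Delayed-release n=5 configuration calibrated to 46 bp/s."""
    return calibrate_prefactor(hairpin, SimulationConfig(), profile)


@pytest.fixture(scope="session")
def meas():
    return MeasurementConfig()


@pytest.fixture(scope="session")
def atpgs_traces(hairpin, delayed_config, meas):
    """Analog-slowed noisy traces (50% ATPgS, 14 nm noise at 200 Hz)."""
    return generate_trace_set(
        hairpin, delayed_config, meas, n_traces=8, seed=7,
        atpgs=dict(atp_mM=0.5, atpgs_mM=0.5, k_ratio=1.2, k_off_per_s=2.5, C=1.0),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
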