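import numpy as np
import pytest

from n2mbw.domain import default_profile
from n2mbw.simulate import (LungParams, SensorChainParams, generate_cohort,
                            simulate_subject)

try:
    from hypothesis import settings, HealthCheck
    settings.register_profile(
        "ci", deadline=None, derandomize=True,
        suppress_health_check=[HealthCheck.too_slow])
    settings.load_profile("ci")
except ImportError:  # hypothesis is optional for the plain unit tests
    pass


@pytest.fixture(scope="session")
def set2_profile():
    return default_profile(2)


@pytest.fixture(scope="session")
def set3_profile():
    return default_profile(3)


@pytest.fixture(scope="session")
def one_comp_clean(set2_profile):
    """Noise-free 1-compartment washout with an undistorted sensor chain."""
    lung = LungParams(frc_mL=1000.0, vt_mL=300.0, airway_ds_mL=50.0,
                      n_compartments=1, phase2_width_mL=30.0)
    sensors = SensorChainParams(
        noise_sd_fraction=0.0, seed=0, true_o2_delay_ms=0.0,
        true_co2_delay_ms=0.0, o2_response_tau_ms=0.0, co2_response_tau_ms=0.0)
    profile = set2_profile.replace(o2_delay_ms=0.0, co2_delay_ms=0.0,
                                   o2_response_time_ms=0.0)
    trace, gt = simulate_subject(lung, sensors, profile)
    return trace, gt, profile


@pytest.fixture(scope="session")
def one_comp_full(set2_profile):
    """Noise-free 1-compartment washout through the full sensor chain."""
    lung = LungParams(frc_mL=1000.0, vt_mL=300.0, airway_ds_mL=50.0,
                      n_compartments=1, phase2_width_mL=30.0)
    sensors = SensorChainParams(noise_sd_fraction=0.0, seed=0,
                                true_o2_delay_ms=601.0, true_co2_delay_ms=51.0)
    trace, gt = simulate_subject(lung, sensors, set2_profile)
    return trace, gt, set2_profile


@pytest.fixture(scope="session")
def two_comp_full(set3_profile):
    """Noise-free 2-compartment washout with inhomogeneity and skew."""
    lung = LungParams(frc_mL=1300.0, vt_mL=380.0, airway_ds_mL=76.0,
                      n_compartments=2,
                      compartment_volume_fractions=(0.58, 0.42),
                      compartment_ventilation_fractions=(0.84, 0.16),
                      emptying_skew=0.7, phase2_width_mL=130.0)
    sensors = SensorChainParams(noise_sd_fraction=0.0, seed=3,
                                true_o2_delay_ms=618.0, true_co2_delay_ms=60.0)
    trace, gt = simulate_subject(lung, sensors, set3_profile)
    return trace, gt, set3_profile


@pytest.fixture(scope="session")
def cohort_noise_free():
    return generate_cohort(seed=1, noise_sd=0.0)


@pytest.fixture(scope="session")
def cohort_default_noise():
    return generate_cohort(seed=1, noise_sd=0.001)
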