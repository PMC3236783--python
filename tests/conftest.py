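import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cnvassay.simulate import (
    ROLE_PRT_PAIR,
    ROLE_QPCR_REFERENCE,
    ROLE_QPCR_TARGET,
    AssayProfile,
    SampleProfile,
    SimulationConfig,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def target_assay():
    return AssayProfile("PRELID1", 1.0823, 107, ROLE_QPCR_TARGET)


@pytest.fixture
def reference_assay():
    return AssayProfile("RNaseP", 1.0228, 87, ROLE_QPCR_REFERENCE)


@pytest.fixture
def prt_assay():
    return AssayProfile(
        "PRELID1-PRT", 0.95, 299, ROLE_PRT_PAIR, paralog_length=299, reference_copies=2
    )


@pytest.fixture
def noiseless_config():
    """Deterministic configuration: no Ct/area noise, no template sampling."""
    return SimulationConfig(
        n_samples=10,
        cn_distribution={2: 1.0},
        ct_noise_sd=0.0,
        area_noise_cv=0.0,
        poisson_template=False,
        seed=0,
    )


def make_sample(cn=2, mass=5.0, frag=math.inf, sid="S0001"):
    return SampleProfile(sample_id=sid, true_cn=cn, input_mass=mass, mean_fragment_length=frag)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
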