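import numpy as np
import pytest

import odontomatch as om


@pytest.fixture(scope="session")
def default_arch():
    """One default 14-tooth upper arch (fixed participant seed)."""
    return om.generate_arch(om.DentitionParams(), participant_seed=17)


@pytest.fixture(scope="session")
def clean_pm_pair(default_arch):
    """AM arch plus a zero-noise, rigidly displaced PM copy and its truth."""
    deg = om.DegradationParams(noise_sd=0.0, deform_amplitude=0.0,
                               gingiva_extra_sd=0.0)
    pm, truth = om.degrade_to_pm(default_arch, deg, seed=23)
    return default_arch, pm, truth


@pytest.fixture(scope="session")
def arch_cloud(default_arch):
    return om.sample_surface(default_arch, 12000, seed=3)


@pytest.fixture(scope="session")
def mini_cohort():
    return om.make_cohort(2, seed=5)
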