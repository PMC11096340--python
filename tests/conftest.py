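import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aa_phenoscreen.tracking import StimulusSchedule, WellGeometry

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def well() -> WellGeometry:
    return WellGeometry()


@pytest.fixture(scope="session")
def short_schedule() -> StimulusSchedule:
    """One-cycle battery starting immediately, with a 10-min recovery."""
    return StimulusSchedule(acclimation_s=0.0, n_cycles=1, intermission_s=600.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240515)
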