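import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hsplocate import HspVector, bundled_database, case_study_panel
from hsplocate.locator import AbsorbanceMeasurement, MeasurementSet

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def db():
    return bundled_database()


@pytest.fixture(scope="session")
def panel():
    """The bundled 14-solvent case-study absorbance panel."""
    return case_study_panel()


@pytest.fixture(scope="session")
def case_material():
    """Published case-study material HSPs (PTPA163), MPa^1/2."""
    return HspVector(16.81, 5.78, 7.96)


def make_panel(solvents, weights):
    """Build a MeasurementSet from parallel (name, (dD,dP,dH)) and weight lists."""
    return MeasurementSet(
        tuple(
            AbsorbanceMeasurement(solvent=name, absorbance=w, hsp=HspVector(*hsp))
            for (name, hsp), w in zip(solvents, weights)
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
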