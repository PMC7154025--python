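import numpy as np
import pytest
from hypothesis import settings

from pulsetwin.presets import MATERIALS, get_preset

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from pulsetwin.synthetic import calibrated_twin, gen_experiment


@pytest.fixture(scope="session")
def porcine_material():
    return MATERIALS["porcine"]

@pytest.fixture(scope="session")
def pericardial_material():
    return MATERIALS["pericardial"]


@pytest.fixture(scope="session")
def porcine_twin():
    """Calibrated porcine twin (driver fixed-point + periodic solve); shared
    across the suite because the calibration is deterministic."""
    return calibrated_twin(get_preset("porcine"))


@pytest.fixture(scope="session")
def pericardial_twin():
    return calibrated_twin(get_preset("pericardial"))


@pytest.fixture(scope="session")
def porcine_dataset(porcine_twin):
    """50-cycle synthetic porcine experiment, seed 1."""
    return gen_experiment(get_preset("porcine"), n_cycles=50, seed=1,
                          twin=porcine_twin)


@pytest.fixture(scope="session")
def pericardial_dataset(pericardial_twin):
    return gen_experiment(get_preset("pericardial"), n_cycles=50, seed=1,
                          twin=pericardial_twin)


def random_unimodular(rng, scale=0.1):
    """Random deformation gradient with unit determinant."""
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    while np.linalg.det(F) <= 0:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
    return F * np.linalg.det(F) ** (-1.0 / 3.0)
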