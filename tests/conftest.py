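import numpy as np
import pytest
from hypothesis import settings

from ryrgate.kinetic_model import KineticParameters, LigandConcentrations

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params() -> KineticParameters:
    """The packaged default calibration of the gating model."""
    return KineticParameters.default()


@pytest.fixture
def no_ligand() -> LigandConcentrations:
    return LigandConcentrations(0.0, 0.0)


def random_parameters(rng: np.random.Generator, fast: bool = False) -> KineticParameters:
    """Random but physically sane parameter draws.

    ``fast=True`` confines binding/conformational rates to a moderate range so
    a single trajectory equilibrates within desk-scale simulated time.
    """
    lo, hi = (0.05, 2.0) if fast else (1e-3, 1e2)

    def r():
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return KineticParameters(
        k1=r(), k_m1=r(), k2=r(), k_m2=r(), k3=r(), k_m3=r(), k4=r(), k_m4=r(),
        kC=480.0, alpha=float(rng.uniform(0.001, 0.05)),
    )
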