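import hypothesis
import numpy as np
import pytest

from erysim.model_core import ModelConstants, PatientParameters
from erysim.observation import PatientProfile
from erysim.pde_solver import GridConfig

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def healthy_params() -> PatientParameters:
    """Healthy-kidney reference subject: normal lifespan and marrow slopes."""
    return PatientParameters(t_rbc=120.0, e_endo=10.0, t_half=8.0, s_alpha=0.02, s_v=0.08)


@pytest.fixture(scope="session")
def profile() -> PatientProfile:
    return PatientProfile("male", 175.0, 80.0)


@pytest.fixture(scope="session")
def mild_constants() -> ModelConstants:
    """Moderate net rates (|beta - alpha| <= 0.1/day, unit velocities, no
    neocytolysis in play) for solver-accuracy comparisons against the analytic
    exponential profiles."""
    return ModelConstants(
        beta=(0.05, 0.02, 0.05, 0.0, 0.0),
        alpha_bfue=0.01,
        alpha_erythroblast=0.02,
        alpha_marrow_reticulocyte=0.01,
        alpha_min=0.06,
        alpha_max=0.06,      # CFU-E apoptosis constant in E
        v_min=1.0,
        v_max=1.0,           # unit velocity everywhere
        e_neo=5.0,
    )


@pytest.fixture(scope="session")
def transport_constants() -> ModelConstants:
    """Pure transport: no proliferation, no death, unit velocities; a long
    BFU-E domain leaves room for a pulse to travel without touching edges."""
    return ModelConstants(
        maturity_span=(20.0, 6.0, 5.0, 3.0),
        beta=(0.0, 0.0, 0.0, 0.0, 0.0),
        alpha_bfue=0.0,
        alpha_erythroblast=0.0,
        alpha_marrow_reticulocyte=0.0,
        alpha_min=0.0,
        alpha_max=0.0,
        v_min=1.0,
        v_max=1.0,
        alpha_neo=0.0,
    )


@pytest.fixture(scope="session")
def coarse_grid() -> GridConfig:
    return GridConfig.coarse()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20130107)
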