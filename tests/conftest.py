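import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thymoquant as tq

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def e155_scenario():
    return tq.make_scenario("E15.5")


@pytest.fixture(scope="session")
def p10_scenario():
    return tq.make_scenario("P10")


@pytest.fixture(scope="session")
def medulla_only_scenario():
    """All-medulla field at the P10 medullary TEC density (5 per 10^4 um^2)."""
    return tq.make_scenario(
        "custom", cortical_tec_density=0.0, medullary_tec_density=5.0,
        cortex_area_fraction=0.0, thymocyte_density_cortex=0.0,
        thymocyte_density_medulla=60.0, organ_volume=55.5)


@pytest.fixture(scope="session")
def p10_section():
    """One rendered P10 section plus ground truth, shared across tests."""
    scn = tq.make_scenario("P10")
    return tq.render_section(scn, field_size=(600.0, 600.0), seed=0)


@pytest.fixture(scope="session")
def e155_section():
    scn = tq.make_scenario("E15.5")
    return tq.render_section(scn, field_size=(600.0, 600.0), seed=0)


def iou(labels: np.ndarray, reference: np.ndarray, lab: int) -> float:
    inter = np.count_nonzero((labels == lab) & (reference == lab))
    union = np.count_nonzero((labels == lab) | (reference == lab))
    return inter / union if union else 1.0
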