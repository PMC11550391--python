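import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hrid import (PreprocessConfig, SignalRecord, make_model, preprocess,
                  simulate)
from hrid.synthetic import PRBSConfig, generate_prbs

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

#: parameter sets in the ballpark of the treadmill estimates, one per
#: structure (distinct poles, so closed-form partial fractions apply)
TM_LIKE_PARAMS = {
    "P1": {"k": 28.6, "tau1": 70.6},
    "P1D": {"k": 25.0, "tau1": 47.7, "Td": 13.1},
    "P2": {"k": 24.7, "tau1": 18.6, "tau2": 37.8},
    "P2D": {"k": 23.9, "tau1": 13.7, "tau2": 37.8, "Td": 5.4},
    "P2Z": {"k": 24.1, "tau1": 24.9, "tau2": 40.2, "Tz": 7.3},
    "P2ZD": {"k": 23.7, "tau1": 33.2, "tau2": 50.6, "Tz": 38.4, "Td": 11.1},
    "P1parP1D": {"kp1": 7.0, "taup1": 141.5,
                 "kp2": 20.2, "taup2": 34.3, "Td": 17.9},
}


@pytest.fixture(scope="session")
def tm_prbs_input():
    """A default-design treadmill PRBS input (1800 s at 5 s)."""
    return generate_prbs(PRBSConfig(low_level=1.2, high_level=2.0, seed=3))


def noise_free_record(structure: str, params: dict, u: np.ndarray,
                      subject_id: str = "S01", test_index: int = 1,
                      baseline: float = 140.0) -> SignalRecord:
    """Absolute-units record simulated exactly from a known model."""
    y = baseline + simulate(make_model(structure, params), u - u.mean(), 5.0)
    return SignalRecord(subject_id=subject_id, test_index=test_index,
                        modality="TM", sample_period=5.0, u=u, y=y)


@pytest.fixture()
def centered_p1d_record(tm_prbs_input):
    rec = noise_free_record("P1D", TM_LIKE_PARAMS["P1D"], tm_prbs_input)
    return preprocess(rec, PreprocessConfig())
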