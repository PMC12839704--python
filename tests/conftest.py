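import numpy as np
import pytest

import spiroqc as s
from spiroqc.experiments import cough_detection_experiment


@pytest.fixture(scope="session")
def clean_maneuver():
    return s.simulate_maneuver(
        s.ManeuverParams(fvc=4.0, pef=8.0, rise_time=0.1, decay_tau=0.6, duration=6.0)
    )


@pytest.fixture(scope="session")
def case_demographics():
    # the worked-example patient: woman, 45 y, BMI 18.1 kg/m2
    return s.Demographics(sex="woman", age=45, bmi=18.1)


@pytest.fixture(scope="session")
def clean_report(clean_maneuver, case_demographics):
    return s.render_report(clean_maneuver, case_demographics)


@pytest.fixture(scope="session")
def clean_construct(clean_report):
    return s.build_construct(clean_report.page, clean_report.demographics)


@pytest.fixture(scope="session")
def cough_experiment():
    """Scaled-down end-to-end run shared by the slow tests (built once)."""
    return cough_detection_experiment()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
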