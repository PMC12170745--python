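import numpy as np
import pytest

from gliosurv import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient strong-signal cohort shared across pipeline tests."""
    cfg = synthetic.strong_signal_config(n_patients=40, seed=11)
    return synthetic.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def censored_outcomes():
    """Handmade 10-subject outcome set with two censored subjects."""
    time = np.array([1.0, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 6.0, 7.0])
    event = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 1])
    risk = np.array([2.1, 1.7, 0.3, 1.2, -0.4, 0.9, 0.1, -1.0, -0.2, -1.5])
    return time, event, risk
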