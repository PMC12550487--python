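import numpy as np
import pytest

import molpred as mp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_scenario():
    """2 prey x 2 predators with mixed rates and digestion curves."""
    return mp.SimulationScenario(
        prey=("aphid", "slug"), predators=("AA", "BB"),
        beta0=np.array([[2.0, 1.0], [0.5, 1.5]]),
        beta1=np.array([[0.10, 0.08], [0.15, 0.12]]),
        lam=np.array([[0.05, 0.02], [0.01, 0.08]]),
        field_n=np.array([120, 60]),
        lab_times=(2.0, 8.0, 24.0, 48.0), lab_n=6, seed=31)


@pytest.fixture(scope="session")
def tiny_data(tiny_scenario):
    lab = mp.simulate_feeding_trial(tiny_scenario)
    field = mp.simulate_field_tests(tiny_scenario)
    return lab, field


@pytest.fixture(scope="session")
def single_pair_fit():
    """One predator-prey pair with known truth, fitted once per session.

    Truth: beta0=2, beta1=0.1, lam=0.05/h (1.2 events/day); 100 lab
    tests over six delays, 500 field captures.
    """
    scn = mp.SimulationScenario(
        prey=("springtail",), predators=("PoCu",),
        beta0=np.array([[2.0]]), beta1=np.array([[0.1]]),
        lam=np.array([[0.05]]), field_n=np.array([500]),
        lab_times=(2.0, 8.0, 16.0, 24.0, 48.0, 72.0), lab_n=17, seed=11)
    lab = mp.simulate_feeding_trial(scn)
    field = mp.simulate_field_tests(scn)
    res = mp.PredationModel(lab, field).fit(
        draws=500, warmup=500, chains=3, seed=1)
    return scn, lab, field, res
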