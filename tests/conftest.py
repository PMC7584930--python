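import numpy as np
import pytest

from sifi.simulator import SimulationParams, simulate_dataset
from sifi.survival_data import CONTROL, EXPERIMENTAL, SurvivalDataset


def make_trial(seed, n=120, beta=-0.6, anc_cens=2.0, **kwargs):
    """Simulated two-arm Weibull trial, deterministic in seed."""
    return simulate_dataset(
        SimulationParams(n=n, beta=beta, seed=seed, anc_cens=anc_cens, **kwargs)
    )


def significant_trials(n_trials, alpha=0.05, n=120, beta=-0.6, start_seed=0):
    """First ``n_trials`` seeds whose trial is significant at ``alpha``."""
    from sifi.logrank import logrank_test

    out = []
    seed = start_seed
    while len(out) < n_trials:
        ds = make_trial(seed, n=n, beta=beta)
        if logrank_test(ds).p_value < alpha:
            out.append(ds)
        seed += 1
    return out


@pytest.fixture
def toy_dataset():
    """Six subjects, hand-enumerable risk sets."""
    return SurvivalDataset.from_arrays(
        time=[1.0, 3.0, 5.0, 2.0, 4.0, 6.0],
        event=[True, True, False, True, True, True],
        arm=[EXPERIMENTAL] * 3 + [CONTROL] * 3,
    )


@pytest.fixture
def significant_dataset():
    """A clearly significant simulated trial (p << .05)."""
    ds = make_trial(3, n=160, beta=-0.8)
    from sifi.logrank import logrank_test

    assert logrank_test(ds).p_value < 0.01
    return ds


@pytest.fixture
def nonsignificant_dataset():
    """A null trial (p >= .05)."""
    ds = make_trial(0, n=120, beta=0.0)
    from sifi.logrank import logrank_test

    assert logrank_test(ds).p_value >= 0.05
    return ds


@pytest.fixture
def identical_arms_dataset():
    """Both arms share one time/event multiset, so p = 1 exactly."""
    times = [1.0, 2.0, 3.0, 4.0, 5.0]
    events = [True, True, False, True, True]
    return SurvivalDataset.from_arrays(
        time=times * 2,
        event=events * 2,
        arm=[EXPERIMENTAL] * 5 + [CONTROL] * 5,
    )
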