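import numpy as np
import pytest

import clickddm as cd
from clickddm.likelihood import GridConfig


@pytest.fixture(scope="session")
def generic_params():
    """Interior, mildly asymmetric parameters exercising every mechanism."""
    return cd.ModelParams(
        lam=-0.4,
        sigma2_a=2.5,
        sigma2_s_ipsi=0.6,
        sigma2_s_contra=1.1,
        bound_B=6.2,
        phi=0.35,
        tau_phi=0.08,
        bias_thresh=0.3,
        lapse_total=0.2,
        lapse_biased=-0.04,
        input_gain=0.55,
    )


@pytest.fixture(scope="session")
def symmetric_params():
    return cd.ModelParams.symmetric(
        lam=-0.3, sigma2_a=2.0, sigma2_s=1.0, bound_B=7.0, phi=0.5, tau_phi=0.08, lapse=0.2
    )


@pytest.fixture(scope="session")
def small_session(symmetric_params):
    """60 accumulation trials with model-generated choices."""
    sess = cd.generate_stimulus_session(60, seed=7, motor_fraction=0.0)
    cd.simulate_session_choices(sess, symmetric_params, seed=8)
    return sess


@pytest.fixture(scope="session")
def fast_grid():
    return GridConfig(dt=0.02, n_bins=61)


def make_trial(left, right, duration):
    return cd.ClickTrial(
        left_clicks=np.asarray(left, dtype=float),
        right_clicks=np.asarray(right, dtype=float),
        duration=duration,
        rate_left=max(len(left) / duration, 1e-9),
        rate_right=max(len(right) / duration, 1e-9),
    )


@pytest.fixture(scope="session")
def trial_factory():
    return make_trial
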