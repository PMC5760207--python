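import dataclasses

import numpy as np
import pytest

from statepop import AnalysisConfig, GeneratorParams, filter_trials, generate_session


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_session(config):
    """8 neurons x 400 trials, default (paper-like) generator."""
    return filter_trials(
        generate_session(GeneratorParams(n_trials=400, n_neurons=8, seed=3)), config
    )


@pytest.fixture(scope="session")
def paper_like_session(config):
    """12 neurons x 800 trials, the study-scale single-session condition."""
    return filter_trials(
        generate_session(GeneratorParams(n_trials=800, n_neurons=12, seed=42)), config
    )


@pytest.fixture(scope="session")
def null_params():
    """Generator with no state dependence anywhere (behavior, gain, noise)."""
    from statepop import BehaviorLink

    return GeneratorParams(
        n_trials=800,
        n_neurons=12,
        behavior_link=BehaviorLink(d_eff_low=0.8, d_eff_high=0.8),
        evoked_gain_slope=0.0,
        shared_noise_lowhigh=(0.1, 0.1),
        seed=7,
    )


def make_manual_session(
    counts: dict, outcomes=None, delta=None, window_ms=None, session_id="manual"
):
    """Hand-built SessionData for targeted oracle tests (fills in any missing
    core epochs with zeros and default metadata)."""
    from statepop import SessionData, TrialInfo

    n_trials, n_neurons = next(iter(counts.values())).shape
    full = dict(counts)
    for epoch in ("pre_target", "pre_test", "target_evoked", "test_evoked"):
        full.setdefault(epoch, np.zeros((n_trials, n_neurons), dtype=int))
    wm = {"pre_target": 200.0, "pre_test": 200.0, "target_evoked": 400.0,
          "test_evoked": 300.0}
    if window_ms:
        wm.update(window_ms)
    outcomes = outcomes if outcomes is not None else ["correct"] * n_trials
    delta = delta if delta is not None else [5.0] * n_trials
    trials = [
        TrialInfo(
            trial_index=t,
            target_orientation=45.0,
            delta_theta=float(delta[t]),
            is_match=delta[t] == 0,
            delay_ms=1050.0,
            delay_mode="fixed",
            outcome=outcomes[t],
        )
        for t in range(n_trials)
    ]
    return SessionData(
        session_id=session_id, counts=full, window_ms=wm, trials=trials
    )
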