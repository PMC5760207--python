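"""Synthetic session generator.

Emulates the statistical structure of trial-structured V1 recordings during a
delayed match-to-sample orientation task:

* unimodal per-neuron pre-stimulus rate distributions with no across-trial
  autocorrelation — a log-normal rate modulation driven by a latent shared
  state drawn i.i.d. per trial;
* a heterogeneous cell-to-population coupling spectrum (per-neuron c_i);
* state-dependent evoked gain (higher evoked rates in the high state);
* state-dependent shared noise (higher spike-count correlations in the high
  state);
* a state-dependent behavioral accuracy link (better performance in the low
  state).

Generative model, per trial t and neuron i (window length w seconds):

    s_t ~ N(0, 1)                                 latent shared state, i.i.d.
    pre rate    lam_it = b_i * exp(sd * (c_i s_t + sqrt(1 - c_i^2) eta_it))
    pre counts  ~ Poisson(lam_it * w)
    evoked rate = f_i(theta) * max(1 + g s_t, eps) * exp(sig z_t - sig^2/2)
    evoked counts ~ Poisson(rate * w)
    P(correct)  = Phi(d_eff / 2) (1 - lapse) + lapse / 2,
                  d_eff = d_low if s_t < 0 else d_high

where f_i is a Gaussian-shaped orientation tuning curve, g the evoked gain
slope, and sig the shared-gain SD chosen by sign(s_t) (low < high).  The
latent state and planted parameters are stored in the session provenance so
downstream stages can be tested by parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .core_io import LADDER_OFFSETS, SessionData, TrialInfo, ladder_epoch

_RATE_FLOOR = 5.0  # spks/s untuned evoked floor keeps rates positive
_GAIN_EPS = 0.1  # lower clip of the state-dependent evoked gain


@dataclass
class BehaviorLink:
    """Mapping from latent state sign to discrimination accuracy.

    ``d_eff_low``/``d_eff_high`` are effective sensitivities in the low/high
    state (accuracy = Phi(d_eff/2) adjusted for lapses); ``lapse`` is the
    state-independent lapse rate.  With ``difficulty_exponent`` > 0 the MEAN
    sensitivity is scaled by (|delta_theta| / max delta)^exponent on
    non-match trials while the state shift stays additive, so harder
    discriminations sit closer to chance where the same state shift moves
    accuracy more (the ceiling effect seen in real psychophysics).
    """

    d_eff_low: float = 1.1
    d_eff_high: float = 0.55
    lapse: float = 0.05
    difficulty_exponent: float = 0.0


@dataclass
class GeneratorParams:
    """Parameters of the synthetic session model (defaults are the study
    conditions the generator is meant to emulate; see docs/methods.md)."""

    n_trials: int = 400
    n_neurons: int = 10
    baseline_rate: np.ndarray | float | None = None  # spks/s; None -> drawn
    state_sd: float = 0.6
    coupling: np.ndarray | float | None = None  # c_i in [0,1]; None -> Beta(2,1.4)
    evoked_gain_slope: float = 0.10
    shared_noise_lowhigh: tuple[float, float] = (0.05, 0.15)
    tuning_peak_rate: float = 30.0
    tuning_bandwidth: float = 30.0  # degrees
    behavior_link: BehaviorLink = field(default_factory=BehaviorLink)
    memory_leak: float = 0.0
    delta_thetas: tuple[float, ...] = (5.0, 10.0)
    target_orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    delay_mode: str = "fixed"  # fixed: 1050 ms; random: U(250, 750) ms
    pre_window_ms: float = 200.0
    target_window_ms: float = 400.0
    test_window_ms: float = 300.0
    store_ladder: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials < 4 or self.n_trials % 2:
            raise ValueError("n_trials must be even and >= 4")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.coupling is not None:
            c = np.atleast_1d(np.asarray(self.coupling, dtype=float))
            if np.any((c < 0) | (c > 1)):
                raise ValueError("coupling values must lie in [0, 1]")
        lo, hi = self.shared_noise_lowhigh
        if lo < 0 or hi < 0 or lo > hi:
            raise ValueError("shared_noise_lowhigh must satisfy 0 <= low <= high")
        bl = self.behavior_link
        if not 0 <= bl.lapse < 1:
            raise ValueError("lapse must lie in [0, 1)")
        for d in (bl.d_eff_low, bl.d_eff_high):
            acc = norm.cdf(d / 2) * (1 - bl.lapse) + 0.5 * bl.lapse
            if not 0.5 < acc < 1:
                raise ValueError(
                    "behavior_link must imply accuracy in (0.5, 1); "
                    f"d_eff={d} gives {acc:.3f}"
                )
        if self.delay_mode not in ("fixed", "random"):
            raise ValueError(f"unknown delay_mode {self.delay_mode!r}")
        if not 0 <= self.memory_leak < 1:
            raise ValueError("memory_leak must lie in [0, 1)")


def _tuning(
    pref: np.ndarray, theta: np.ndarray, peak: float, bw: np.ndarray | float
) -> np.ndarray:
    """Gaussian-shaped orientation tuning on the wrapped difference in
    [0, 90] degrees; returns rates (trials x neurons) in spks/s.  ``bw`` may
    be per-trial (column vector) to express state-dependent tuning width."""
    d = np.abs(theta[:, None] - pref[None, :]) % 180.0
    d = np.minimum(d, 180.0 - d)
    return _RATE_FLOOR + (peak - _RATE_FLOOR) * np.exp(-(d**2) / (2 * np.asarray(bw) ** 2))


def _pre_counts(
    rng: np.random.Generator,
    baseline: np.ndarray,
    coupling: np.ndarray,
    state_sd: float,
    s: np.ndarray,
    win_s: float,
) -> np.ndarray:
    eta = rng.standard_normal((s.size, baseline.size))
    shared = coupling[None, :] * s[:, None]
    private = np.sqrt(1.0 - coupling**2)[None, :] * eta
    lam = baseline[None, :] * np.exp(state_sd * (shared + private))
    return rng.poisson(lam * win_s)


def generate_session(params: GeneratorParams, session_id: str = "S0") -> SessionData:
    """Draw one synthetic session; identical parameters (incl. seed) yield an
    identical session."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, m = params.n_trials, params.n_neurons

    baseline = params.baseline_rate
    if baseline is None:
        baseline = rng.lognormal(mean=np.log(12.0), sigma=0.45, size=m)
    baseline = np.broadcast_to(np.atleast_1d(np.asarray(baseline, float)), (m,)).copy()

    coupling = params.coupling
    if coupling is None:
        coupling = rng.beta(2.0, 1.4, size=m)
    coupling = np.broadcast_to(np.atleast_1d(np.asarray(coupling, float)), (m,)).copy()

    pref = rng.uniform(0.0, 180.0, size=m)

    # trial metadata: half match, half non-match with random signed delta
    is_match = np.zeros(n, dtype=bool)
    is_match[rng.permutation(n)[: n // 2]] = True
    theta_t = rng.choice(params.target_orientations, size=n)
    delta = np.where(
        is_match,
        0.0,
        rng.choice(params.delta_thetas, size=n) * rng.choice([-1.0, 1.0], size=n),
    )
    if params.delay_mode == "fixed":
        delay = np.full(n, 1050.0)
    else:
        delay = np.round(rng.uniform(250.0, 750.0, size=n))

    pre_w = params.pre_window_ms / 1000.0
    counts: dict[str, np.ndarray] = {}
    window_ms: dict[str, float] = {}

    # pre-test ladder: each 200-ms window gets its own i.i.d. latent state;
    # the offset-0 state is the one behavior and evoked gain are linked to
    s_t = rng.standard_normal(n)
    counts["pre_test"] = _pre_counts(rng, baseline, coupling, params.state_sd, s_t, pre_w)
    window_ms["pre_test"] = params.pre_window_ms
    offsets = LADDER_OFFSETS[1:] if params.store_ladder else ()
    for off in offsets:
        s_off = rng.standard_normal(n)
        epoch = ladder_epoch("pre_test", off)
        counts[epoch] = _pre_counts(rng, baseline, coupling, params.state_sd, s_off, pre_w)
        window_ms[epoch] = params.pre_window_ms

    s_pre_target = rng.standard_normal(n)
    counts["pre_target"] = _pre_counts(
        rng, baseline, coupling, params.state_sd, s_pre_target, pre_w
    )
    window_ms["pre_target"] = params.pre_window_ms

    if params.memory_leak > 0:
        # orientation memory trace in the pre-test window
        d = np.abs(theta_t[:, None] - pref[None, :]) % 180.0
        d = np.minimum(d, 180.0 - d)
        leak = 1.0 + params.memory_leak * np.cos(2 * np.deg2rad(d))
        # redraw pre_test with the leak folded into the rate
        eta = rng.standard_normal((n, m))
        shared = coupling[None, :] * s_t[:, None]
        private = np.sqrt(1.0 - coupling**2)[None, :] * eta
        lam = baseline[None, :] * np.exp(params.state_sd * (shared + private)) * leak
        counts["pre_test"] = rng.poisson(lam * pre_w)

    # evoked epochs: tuning x state gain x shared multiplicative noise with a
    # state-dependent SD (low < high), so evoked rates and correlated
    # variability both rise with the latent state
    gain_state = np.maximum(1.0 + params.evoked_gain_slope * s_t, _GAIN_EPS)
    sig = np.where(s_t < 0, params.shared_noise_lowhigh[0], params.shared_noise_lowhigh[1])
    for epoch, theta, win_ms in (
        ("target_evoked", theta_t, params.target_window_ms),
        ("test_evoked", theta_t + delta, params.test_window_ms),
    ):
        z = rng.standard_normal(n)
        g_shared = np.exp(sig * z - sig**2 / 2.0)
        rate = _tuning(pref, np.asarray(theta, float), params.tuning_peak_rate,
                       params.tuning_bandwidth)
        rate = rate * (gain_state * g_shared)[:, None]
        counts[epoch] = rng.poisson(rate * (win_ms / 1000.0))
        window_ms[epoch] = win_ms

    # behavior: accuracy set by the sign of the offset-0 pre-test state
    bl = params.behavior_link
    d_mean = (bl.d_eff_low + bl.d_eff_high) / 2.0
    d_shift = (bl.d_eff_low - bl.d_eff_high) / 2.0
    scale = np.ones(n)
    if bl.difficulty_exponent > 0:
        nonmatch = ~is_match
        scale[nonmatch] = (
            np.abs(delta[nonmatch]) / max(params.delta_thetas)
        ) ** bl.difficulty_exponent
    d_eff = np.maximum(
        d_mean * scale + np.where(s_t < 0, d_shift, -d_shift), 0.05
    )
    p_correct = norm.cdf(d_eff / 2.0) * (1 - bl.lapse) + 0.5 * bl.lapse
    correct = rng.random(n) < p_correct

    trials = [
        TrialInfo(
            trial_index=t,
            target_orientation=float(theta_t[t]),
            delta_theta=float(delta[t]),
            is_match=bool(is_match[t]),
            delay_ms=float(delay[t]),
            delay_mode=params.delay_mode,
            outcome="correct" if correct[t] else "incorrect",
        )
        for t in range(n)
    ]

    prov = {
        "kind": "synthetic",
        "seed": int(params.seed),
        "latent_state": s_t.tolist(),
        "p_correct": p_correct.tolist(),
        "coupling": coupling.tolist(),
        "baseline_rate": baseline.tolist(),
        "pref_orientation": pref.tolist(),
        "params": _params_dict(params),
    }
    return SessionData(
        session_id=session_id,
        counts=counts,
        window_ms=window_ms,
        trials=trials,
        provenance=prov,
    )


def _params_dict(params: GeneratorParams) -> dict:
    d = dataclasses.asdict(params)
    for key in ("baseline_rate", "coupling"):
        if isinstance(d[key], np.ndarray):
            d[key] = d[key].tolist()
    return d


def session_seed(master_seed: int, session_index: int) -> int:
    """Reproducible per-session seed derived from a cohort master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(session_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    params: GeneratorParams,
    n_sessions: int,
    master_seed: int,
    neuron_range: tuple[int, int] | None = None,
) -> list[SessionData]:
    """Independent sessions with per-session seeds derived from
    ``master_seed``.  ``neuron_range=(lo, hi)`` jitters n_neurons per session
    (inclusive bounds), mimicking variable yield across recordings."""
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    jitter_rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), 997]))
    sessions = []
    for i in range(n_sessions):
        p = dataclasses.replace(params, seed=session_seed(master_seed, i))
        if neuron_range is not None:
            p = dataclasses.replace(
                p, n_neurons=int(jitter_rng.integers(neuron_range[0], neuron_range[1] + 1))
            )
        sessions.append(generate_session(p, session_id=f"S{i:03d}"))
    return sessions
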