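"""Pre-stimulus window counting, normalization, median-split state labels,
and single-neuron descriptive statistics (evoked rate by state, Fano factor,
trial autocorrelation).

The central object is the *state label*: each trial is classified low or high
by a rank-based median split of ongoing activity in a 200-ms window before
stimulus onset, guaranteeing exactly equal trial counts in the two states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    AnalysisConfig,
    MissingEpochError,
    SessionData,
    ladder_epoch,
)

LOW, HIGH = "low", "high"


@dataclass
class StateLabels:
    """Per-trial low/high assignment.

    ``high`` is a boolean array (True = high state).  ``source_neurons`` is
    the index set whose pooled activity defined the split.
    """

    high: np.ndarray
    source_neurons: tuple[int, ...]
    median_value: float
    alignment: str = "pre_test"
    window_offset_ms: int = 0

    @property
    def labels(self) -> np.ndarray:
        return np.where(self.high, HIGH, LOW)

    @property
    def n_trials(self) -> int:
        return self.high.size

    def low_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.high)

    def high_idx(self) -> np.ndarray:
        return np.flatnonzero(self.high)


@dataclass
class Autocorrelation:
    """Trial-lag autocorrelation with its white-noise 95% band."""

    acf: np.ndarray  # index = lag, acf[0] == 1
    band: np.ndarray  # +/- band half-width per lag

    def within_band(self) -> np.ndarray:
        """Boolean per lag >= 1: |acf| inside the 95% white-noise band."""
        return np.abs(self.acf[1:]) <= self.band[1:]


@dataclass
class StateMetrics:
    """Per-neuron descriptive statistics of the low/high split."""

    neuron_id: str
    pre_rate_mean: float
    pre_rate_low: float
    pre_rate_high: float
    rate_change: float  # pre_rate_high - pre_rate_low, spks/s
    evoked_low: float
    evoked_high: float
    fano_low: float
    fano_high: float


def window_counts(
    session: SessionData, alignment: str, window_offset_ms: int = 0
) -> np.ndarray:
    """Integer counts in the 200-ms window ending ``window_offset_ms`` before
    the aligned stimulus onset (offset 0 = immediately preceding onset)."""
    epoch = ladder_epoch(alignment, window_offset_ms)
    if epoch not in session.counts:
        raise MissingEpochError(
            f"session {session.session_id!r} does not store epoch {epoch!r}"
        )
    return session.counts[epoch]


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Map per-trial values to [0, 1]: (v - min) / (max - min).

    A constant vector maps to all 0.5.  With a 2-D input the normalization is
    applied independently per column (neuron).
    """
    v = np.asarray(values, dtype=float)
    if v.shape[0] < 2:
        raise ValueError("need at least 2 trials to normalize")
    lo = v.min(axis=0)
    span = v.max(axis=0) - lo
    out = np.where(span == 0, 0.5, (v - lo) / np.where(span == 0, 1.0, span))
    return out


def median_split(
    values: np.ndarray,
    source_neurons: tuple[int, ...] = (),
    alignment: str = "pre_test",
    window_offset_ms: int = 0,
) -> StateLabels:
    """Rank-based median split: the n/2 smallest values are labeled low, the
    n/2 largest high.  Ties at the median are broken by trial order (earlier
    trial goes to low), so the two halves are exactly equal in size.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n % 2 != 0:
        raise ValueError(f"median_split requires an even trial count, got {n}")
    order = np.argsort(v, kind="stable")  # stable => earlier ties ranked lower
    high = np.zeros(n, dtype=bool)
    high[order[n // 2 :]] = True
    return StateLabels(
        high=high,
        source_neurons=tuple(source_neurons),
        median_value=float(np.median(v)),
        alignment=alignment,
        window_offset_ms=window_offset_ms,
    )


def evoked_rates_by_state(
    session: SessionData,
    labels: StateLabels,
    subtract_baseline: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron mean test-evoked rate (spks/s) in low vs high trials.

    With ``subtract_baseline`` the same-trial pre-stimulus rate is subtracted
    from each trial's evoked rate first.
    """
    rates = session.rates("test_evoked").astype(float)
    if subtract_baseline:
        rates = rates - session.rates("pre_test")
    lo, hi = labels.low_idx(), labels.high_idx()
    return rates[lo].mean(axis=0), rates[hi].mean(axis=0)


def fano_factor(counts: np.ndarray, groups: np.ndarray | None = None) -> float | dict:
    """Variance-to-mean ratio of spike counts.

    With ``groups`` given, FF is computed within each group and returned as a
    dict; a group with mean 0 (or < 2 trials) yields ``nan`` rather than an
    error.  Without groups, a single FF for the whole vector.
    """
    c = np.asarray(counts, dtype=float)
    if groups is None:
        return _ff(c)
    groups = np.asarray(groups)
    return {g: _ff(c[groups == g]) for g in pd.unique(groups)}


def _ff(c: np.ndarray) -> float:
    if c.size < 2:
        return float("nan")
    m = c.mean()
    if m == 0:
        return float("nan")
    return float(c.var(ddof=1) / m)


def evoked_fano_by_state(
    session: SessionData,
    labels: StateLabels,
    neuron: int,
    within_condition: bool = True,
) -> tuple[float, float]:
    """Fano factor of test-evoked counts in the low and high states.

    By default FF is computed within each stimulus condition (target
    orientation x delta-theta cell) and then averaged across conditions per
    state, so stimulus-driven mean differences do not inflate the variance.
    """
    counts = session.counts["test_evoked"][:, neuron].astype(float)
    table = session.trial_table()
    cond = list(zip(table.target_orientation, table.delta_theta))
    cond = pd.Series(cond).astype(str).to_numpy()
    out = []
    for idx in (labels.low_idx(), labels.high_idx()):
        if not within_condition:
            out.append(_ff(counts[idx]))
            continue
        ffs = [
            _ff(counts[idx][cond[idx] == g])
            for g in pd.unique(cond[idx])
        ]
        ffs = [f for f in ffs if np.isfinite(f)]
        out.append(float(np.mean(ffs)) if ffs else float("nan"))
    return out[0], out[1]


def trial_autocorrelation(values: np.ndarray, max_lag: int = 20) -> Autocorrelation:
    """Pearson correlation of a per-trial series with its lag-k shift,
    k = 0..max_lag, with the +/-1.96/sqrt(n-k) white-noise 95% band.

    A constant series yields nan correlations (zero variance).
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n <= max_lag + 2:
        raise ValueError(f"need n_trials > max_lag + 2 (n={n}, max_lag={max_lag})")
    acf = np.empty(max_lag + 1)
    band = np.empty(max_lag + 1)
    acf[0], band[0] = 1.0, 1.96 / np.sqrt(n)
    for k in range(1, max_lag + 1):
        a, b = v[:-k], v[k:]
        if a.std() == 0 or b.std() == 0:
            acf[k] = float("nan")
        else:
            acf[k] = float(np.corrcoef(a, b)[0, 1])
        band[k] = 1.96 / np.sqrt(n - k)
    if v.std() == 0:
        acf[0] = float("nan")
    return Autocorrelation(acf=acf, band=band)


def state_metrics(
    session: SessionData, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-neuron low/high descriptive statistics, each neuron split by its
    own pre-stimulus activity (the single-cell view of the state analysis)."""
    config = config or AnalysisConfig()
    pre = window_counts(session, config.alignment, config.window_offset_ms)
    win_s = session.window_ms[ladder_epoch(config.alignment, config.window_offset_ms)] / 1000.0
    rows = []
    for i, nid in enumerate(session.neuron_ids):
        labels = median_split(pre[:, i], source_neurons=(i,))
        pre_rates = pre[:, i] / win_s
        ev_lo, ev_hi = evoked_rates_by_state(
            session, labels, subtract_baseline=config.subtract_baseline
        )
        f_lo, f_hi = evoked_fano_by_state(session, labels, i)
        lo_mean = float(pre_rates[labels.low_idx()].mean())
        hi_mean = float(pre_rates[labels.high_idx()].mean())
        rows.append(
            StateMetrics(
                neuron_id=nid,
                pre_rate_mean=float(pre_rates.mean()),
                pre_rate_low=lo_mean,
                pre_rate_high=hi_mean,
                rate_change=hi_mean - lo_mean,
                evoked_low=float(ev_lo[i]),
                evoked_high=float(ev_hi[i]),
                fano_low=f_lo,
                fano_high=f_hi,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def kde_mode_count(
    values: np.ndarray,
    rel_prominence: float = 0.10,
    grid: int = 512,
    min_bandwidth: float = 0.0,
) -> int:
    """Number of prominent modes of a sample's smoothed density.

    A Gaussian KDE (Scott bandwidth, floored at ``min_bandwidth`` in data
    units) is evaluated on a regular grid and local maxima whose prominence
    exceeds ``rel_prominence`` of the peak density are counted.  Used as the
    unimodality diagnostic for pooled pre-stimulus rate distributions (1 mode
    = unimodal); set ``min_bandwidth`` to the quantization step of discrete
    data (e.g. the spks/s value of one spike count) to avoid comb artifacts.
    """
    from scipy.signal import find_peaks

    v = np.asarray(values, dtype=float)
    kde = stats.gaussian_kde(v)
    if min_bandwidth > 0:
        kde.set_bandwidth(max(kde.factor, min_bandwidth / v.std()))
    xs = np.linspace(v.min() - v.std(), v.max() + v.std(), grid)
    dens = kde(xs)
    peaks, _ = find_peaks(dens, prominence=rel_prominence * dens.max())
    return int(len(peaks))
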