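"""Combinatorial subpopulation pooling vs. behavioral performance.

For every pool size k = 1..n, all C(n, k) neuron subsets (capped, seeded
subsampling beyond the cap) define a pooled pre-stimulus trace — the mean of
the member neurons' min-max-normalized counts — whose median split labels
trials low/high.  Behavioral performance in each state, averaged across pools
and normalized by the session-wide performance, quantifies how well pooled
ongoing activity predicts perceptual accuracy as the pool grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AnalysisConfig, SessionData
from .state import median_split, minmax_normalize, window_counts


@dataclass
class PoolingCurve:
    """Session-normalized behavioral performance by state vs pool size."""

    session_id: str
    sizes: np.ndarray
    perf_low_norm: np.ndarray
    perf_high_norm: np.ndarray
    n_pools_used: np.ndarray
    session_performance: float
    alignment: str = "pre_test"
    window_offset_ms: int = 0

    def gap(self) -> np.ndarray:
        """Low-minus-high normalized performance per pool size."""
        return self.perf_low_norm - self.perf_high_norm

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "session_id": self.session_id,
                "k": self.sizes,
                "perf_low_norm": self.perf_low_norm,
                "perf_high_norm": self.perf_high_norm,
                "n_pools_used": self.n_pools_used,
            }
        )


@dataclass
class CohortSummary:
    """Across-session aggregation of pooling curves."""

    per_size: pd.DataFrame  # k, n_sessions, mean/sem low & high, mean gap
    largest_common_size: int
    signed_rank_p: float  # low vs high at the largest common size
    gap_small: float
    gap_large: float
    bootstrap_p: float  # P(gap_large <= gap_small) over session resamples
    bootstrap_ci: tuple[float, float]  # 95% CI of gap_large - gap_small


def enumerate_pools(
    n: int, k: int, cap: int = 2000, seed: int = 0
) -> list[tuple[int, ...]]:
    """All C(n, k) index subsets in lexicographic order, or ``cap`` distinct
    subsets sampled uniformly without replacement (seeded) when C(n, k) > cap."""
    if not 1 <= k <= n:
        raise ValueError(f"pool size k={k} outside 1..{n}")
    total = comb(n, k)
    if total <= cap:
        from itertools import combinations

        return list(combinations(range(n), k))
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, ...]] = set()
    while len(chosen) < cap:
        chosen.add(tuple(sorted(rng.choice(n, size=k, replace=False).tolist())))
    return sorted(chosen)


def _pool_state_performance(
    norm_counts: np.ndarray, correct: np.ndarray, pools: list[tuple[int, ...]]
) -> tuple[float, float]:
    """Mean fraction correct in low/high trials across pools (vectorized:
    one stable argsort per pool trace, ties to low by trial order)."""
    n_trials = norm_counts.shape[0]
    half = n_trials // 2
    member = np.zeros((norm_counts.shape[1], len(pools)))
    for j, pool in enumerate(pools):
        member[list(pool), j] = 1.0 / len(pool)
    traces = norm_counts @ member  # trials x pools
    order = np.argsort(traces, axis=0, kind="stable")
    p_low = correct[order[:half]].mean(axis=0)
    p_high = correct[order[half:]].mean(axis=0)
    return float(p_low.mean()), float(p_high.mean())


def pooling_curve(
    session: SessionData, config: AnalysisConfig | None = None
) -> PoolingCurve:
    """Behavioral performance by state for pool sizes 1..n (session assumed
    already trial-filtered)."""
    config = config or AnalysisConfig()
    if session.n_trials % 2:
        raise ValueError("pooling_curve requires an even trial count")
    pre = window_counts(session, config.alignment, config.window_offset_ms)
    norm = minmax_normalize(pre.astype(float))
    correct = session.correct_mask().astype(float)
    p_bar = float(correct.mean())
    if p_bar == 0:
        raise ValueError("session has no correct trials; performance undefined")
    n = session.n_neurons
    sizes = np.arange(1, n + 1)
    lows, highs, used = [], [], []
    for k in sizes:
        pools = enumerate_pools(n, int(k), cap=config.pool_cap, seed=config.rng_seed)
        p_low, p_high = _pool_state_performance(norm, correct, pools)
        lows.append(p_low / p_bar)
        highs.append(p_high / p_bar)
        used.append(len(pools))
    return PoolingCurve(
        session_id=session.session_id,
        sizes=sizes,
        perf_low_norm=np.array(lows),
        perf_high_norm=np.array(highs),
        n_pools_used=np.array(used),
        session_performance=p_bar,
        alignment=config.alignment,
        window_offset_ms=config.window_offset_ms,
    )


def window_sweep(
    session: SessionData,
    config: AnalysisConfig | None = None,
    offsets: tuple[int, ...] = (0, 200, 400, 600, 800),
    pool_size: int = 5,
) -> dict[int, float]:
    """Low-vs-high behavioral difference (percent of session performance) when
    the state is read from successively earlier 200-ms windows, at a fixed
    pool size (default 5, capped at n_neurons)."""
    config = config or AnalysisConfig()
    k = min(pool_size, session.n_neurons)
    correct = session.correct_mask().astype(float)
    p_bar = float(correct.mean())
    out = {}
    for off in offsets:
        pre = window_counts(session, config.alignment, off)
        norm = minmax_normalize(pre.astype(float))
        pools = enumerate_pools(
            session.n_neurons, k, cap=config.pool_cap, seed=config.rng_seed
        )
        p_low, p_high = _pool_state_performance(norm, correct, pools)
        out[off] = 100.0 * (p_low - p_high) / p_bar
    return out


def aggregate_cohort(
    curves: list[PoolingCurve],
    n_boot: int = 10_000,
    seed: int = 0,
    small_k: int = 2,
    large_k: int | None = None,
) -> CohortSummary:
    """Across-session mean +/- SEM per pool size (sessions contribute to size
    k only if they recorded >= k neurons), a paired signed-rank low-vs-high
    test at the largest common size, and a percentile bootstrap over sessions
    comparing the low/high gap at a small vs large pool size."""
    if len(curves) < 2:
        raise ValueError("aggregate_cohort needs >= 2 sessions")
    rows = pd.concat([c.to_table() for c in curves], ignore_index=True)
    per_size = (
        rows.groupby("k")
        .agg(
            n_sessions=("session_id", "nunique"),
            perf_low_mean=("perf_low_norm", "mean"),
            perf_low_sem=("perf_low_norm", "sem"),
            perf_high_mean=("perf_high_norm", "mean"),
            perf_high_sem=("perf_high_norm", "sem"),
        )
        .reset_index()
    )
    per_size["gap_mean"] = per_size.perf_low_mean - per_size.perf_high_mean

    k_max_common = int(min(c.sizes.max() for c in curves))
    at_common = rows[rows.k == k_max_common]
    lo = at_common.perf_low_norm.to_numpy()
    hi = at_common.perf_high_norm.to_numpy()
    if np.allclose(lo, hi):
        p_signed = 1.0
    else:
        p_signed = float(stats.wilcoxon(lo, hi).pvalue)

    large_k = k_max_common if large_k is None else min(large_k, k_max_common)
    small_k = min(small_k, large_k)
    gaps = rows.assign(gap=rows.perf_low_norm - rows.perf_high_norm)
    g_small = gaps[gaps.k == small_k].set_index("session_id").gap
    g_large = gaps[gaps.k == large_k].set_index("session_id").gap
    common = g_small.index.intersection(g_large.index)
    gs, gl = g_small[common].to_numpy(), g_large[common].to_numpy()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(common), size=(n_boot, len(common)))
    boot_diff = gl[idx].mean(axis=1) - gs[idx].mean(axis=1)
    return CohortSummary(
        per_size=per_size,
        largest_common_size=k_max_common,
        signed_rank_p=p_signed,
        gap_small=float(gs.mean()),
        gap_large=float(gl.mean()),
        bootstrap_p=float(np.mean(boot_diff <= 0)),
        bootstrap_ci=(
            float(np.percentile(boot_diff, 2.5)),
            float(np.percentile(boot_diff, 97.5)),
        ),
    )
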