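"""Cell-to-population coupling: the same-state probability statistic, its
binomial significance bounds, and the state-dependent behavioral change.

For each neuron, trials are split low/high by the cell's own pre-stimulus
activity and, independently, by the mean normalized activity of the remaining
population.  The fraction of trials in which the two labels agree (p_same) is
1 for a cell perfectly synchronized with the population and 0.5 for an
independent cell; significance is assessed against the normal-approximation
binomial confidence interval n*(0.5 +/- 0.98/sqrt(n)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AnalysisConfig, SessionData
from .state import StateLabels, median_split, minmax_normalize, window_counts


@dataclass
class CouplingResult:
    """Per-cell coupling statistics."""

    neuron_id: str
    p_same: float
    n: int
    ci_low_count: float
    ci_high_count: float
    significant: bool
    behavior_delta_pct: float
    population_mean_trace: np.ndarray

    def to_row(self) -> dict:
        return {
            "neuron_id": self.neuron_id,
            "p_same": self.p_same,
            "n": self.n,
            "ci_low_count": self.ci_low_count,
            "ci_high_count": self.ci_high_count,
            "significant": self.significant,
            "behavior_delta_pct": self.behavior_delta_pct,
        }


@dataclass
class CorrelationFit:
    """Pearson correlation with the least-squares line (regression view)."""

    r: float
    p_value: float
    slope: float
    intercept: float
    r_squared: float


def probability_same_state(labels_cell: StateLabels, labels_pop: StateLabels) -> float:
    """Fraction of trials in which two label vectors agree."""
    a, b = labels_cell.high, labels_pop.high
    if a.size != b.size:
        raise ValueError(f"label length mismatch: {a.size} vs {b.size}")
    return float(np.mean(a == b))


def binomial_ci(n: int) -> tuple[float, float]:
    """Chance-level 95% bounds on the same-state trial count:
    n*(0.5 - (1.96/2)/sqrt(n)) and n*(0.5 + (1.96/2)/sqrt(n)), unrounded."""
    if n < 4:
        raise ValueError(f"binomial_ci requires n >= 4, got {n}")
    half = (1.96 / 2.0) * np.sqrt(n)
    return float(n * 0.5 - half), float(n * 0.5 + half)


def behavior_state_delta(
    session: SessionData, labels: StateLabels, config: AnalysisConfig | None = None
) -> float:
    """Percent change in behavioral performance, low vs high state:
    100 * (P_low - P_high) / denominator.

    Positive values mean performance is better in the low pre-stimulus state.
    The denominator is the session-wide fraction correct on the same trials
    (or P_high, selectable via config); 0 denominator yields nan.
    """
    config = config or AnalysisConfig()
    correct = session.correct_mask().astype(float)
    if correct.size != labels.n_trials:
        raise ValueError("labels do not match the session's trial count")
    p_low = float(correct[labels.low_idx()].mean())
    p_high = float(correct[labels.high_idx()].mean())
    denom = float(correct.mean()) if config.behavior_delta_denominator == "session" else p_high
    if denom == 0:
        return float("nan")
    return 100.0 * (p_low - p_high) / denom


def coupling_profile(
    session: SessionData, config: AnalysisConfig | None = None
) -> list[CouplingResult]:
    """Same-state probability and behavioral delta for every neuron.

    The cell's own labels come from a median split of its raw pre-stimulus
    counts; the population trace is the mean of the remaining neurons'
    min-max-normalized counts, median-split in turn.
    """
    config = config or AnalysisConfig()
    if session.n_neurons < 3:
        raise ValueError("coupling_profile needs >= 3 neurons (leave-one-out mean)")
    pre = window_counts(session, config.alignment, config.window_offset_ms)
    norm = minmax_normalize(pre.astype(float))
    n = session.n_trials
    ci_lo, ci_hi = binomial_ci(n)
    results = []
    for i, nid in enumerate(session.neuron_ids):
        cell_labels = median_split(
            pre[:, i], source_neurons=(i,),
            alignment=config.alignment, window_offset_ms=config.window_offset_ms,
        )
        others = [j for j in range(session.n_neurons) if j != i]
        trace = norm[:, others].mean(axis=1)
        pop_labels = median_split(
            trace, source_neurons=tuple(others),
            alignment=config.alignment, window_offset_ms=config.window_offset_ms,
        )
        p = probability_same_state(cell_labels, pop_labels)
        k = p * n
        results.append(
            CouplingResult(
                neuron_id=nid,
                p_same=p,
                n=n,
                ci_low_count=ci_lo,
                ci_high_count=ci_hi,
                significant=bool(k < ci_lo or k > ci_hi),
                behavior_delta_pct=behavior_state_delta(session, cell_labels, config),
                population_mean_trace=trace,
            )
        )
    return results


def coupling_table(results: list[CouplingResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> CorrelationFit:
    """Pearson R of two series with the least-squares regression line.

    Constant input yields nan statistics (missing value, not an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    if x.std() == 0 or y.std() == 0:
        return CorrelationFit(*(float("nan"),) * 5)
    lr = stats.linregress(x, y)
    return CorrelationFit(
        r=float(lr.rvalue),
        p_value=float(lr.pvalue),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r_squared=float(lr.rvalue**2),
    )
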