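"""Fisher-linear-discriminant population decoding.

Target-evoked vs test-evoked population spike counts are separated along the
most discriminant dimension w* = Sw^-1 (u1 - u2), where Sw = S1 + S2 is the
total within-class scatter.  Discriminability is the multivariate d-prime
squared, d2 = dmu' Q^-1 dmu, with Q the pooled covariance; the probability of
correct classification of the optimal linear rule for two homoscedastic
Gaussians at Mahalanobis distance sqrt(d2) is

    PCC = Phi(sqrt(d2) / 2) = 0.5 * erfc(-sqrt(d2) / (2 sqrt(2))).

The correlation-shuffled variant replaces Q by its diagonal.  The module also
provides state-conditioned decoding (fit separately on low/high-labeled
trials, states measured from pools of 1..n neurons), state-conditioned noise
correlations, and a cross-validated control decoding the remembered target
orientation from pre-test activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erfc

from .core_io import AnalysisConfig, SessionData
from .pooling import enumerate_pools
from .state import StateLabels, median_split, minmax_normalize, window_counts

logger = logging.getLogger("statepop")


@dataclass
class FLDModel:
    """Fitted Fisher linear discriminant for two classes of count vectors."""

    w_star: np.ndarray
    u1: np.ndarray
    u2: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    Sw: np.ndarray
    Q: np.ndarray
    ridge: float

    def decision_boundary(self) -> float:
        """Midpoint of the projected class means on w* (visualization aid)."""
        return float(self.w_star @ (self.u1 + self.u2) / 2.0)

    def projection_gaussians(self, X1: np.ndarray, X2: np.ndarray):
        """Maximum-likelihood (mean, SD) of each class's projection onto w*."""
        p1, p2 = X1 @ self.w_star, X2 @ self.w_star
        return (float(p1.mean()), float(p1.std())), (float(p2.mean()), float(p2.std()))


@dataclass
class DecoderResult:
    d2: float
    d_prime: float
    pcc: float
    d2_shuffled: float
    pcc_shuffled: float
    fld_mean_diff: float
    fld_pooled_sigma: float
    state: str = "all"  # {low, high, all}
    pool_size_for_state: int = 0
    n_pools_used: int = 0

    def to_row(self) -> dict:
        return {
            "state": self.state,
            "state_pool_size": self.pool_size_for_state,
            "d2": self.d2,
            "d2_shuffled": self.d2_shuffled,
            "pcc": self.pcc,
            "pcc_shuffled": self.pcc_shuffled,
            "fld_mean_diff": self.fld_mean_diff,
            "fld_pooled_sigma": self.fld_pooled_sigma,
            "n_pools_used": self.n_pools_used,
        }


@dataclass
class NoiseCorrResult:
    """State-conditioned pairwise spike-count (noise) correlations."""

    r_sc_low: float
    r_sc_high: float
    sem_low: float
    sem_high: float
    pair_values_low: np.ndarray
    pair_values_high: np.ndarray
    fraction_negative: float


def pcc_from_d2(d2: float) -> float:
    """Probability of correct classification at squared distance d2."""
    return float(0.5 * erfc(-np.sqrt(max(d2, 0.0)) / (2.0 * np.sqrt(2.0))))


def _regularized_inverse(Q: np.ndarray, ridge: float) -> np.ndarray:
    dim = Q.shape[0]
    if ridge > 0:
        tr = np.trace(Q)
        Qr = Q + ridge * (tr / dim if tr > 0 else 1.0) * np.eye(dim)
        return np.linalg.inv(Qr)
    try:
        return np.linalg.inv(Q)
    except np.linalg.LinAlgError:
        logger.warning("singular scatter matrix with ridge=0; using pseudo-inverse")
        return np.linalg.pinv(Q)


def discriminability_from_moments(
    delta_mu: np.ndarray, Q: np.ndarray, ridge: float = 0.0
) -> DecoderResult:
    """Closed-form decoder metrics from a mean difference and pooled
    covariance (the moment-level core shared by all fitted variants)."""
    delta_mu = np.atleast_1d(np.asarray(delta_mu, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    Qinv = _regularized_inverse(Q, ridge)
    d2 = float(max(delta_mu @ Qinv @ delta_mu, 0.0))
    Qd_inv = np.diag(1.0 / np.diag(Q))
    d2_sh = float(max(delta_mu @ Qd_inv @ delta_mu, 0.0))
    w = Qinv @ delta_mu
    norm = np.linalg.norm(w)
    if norm == 0:
        mean_diff, sigma = 0.0, float(np.sqrt(np.mean(np.diag(Q))))
    else:
        w = w / norm
        mean_diff = float(abs(w @ delta_mu))
        sigma = float(np.sqrt(w @ Q @ w))
    return DecoderResult(
        d2=d2,
        d_prime=float(np.sqrt(d2)),
        pcc=pcc_from_d2(d2),
        d2_shuffled=d2_sh,
        pcc_shuffled=pcc_from_d2(d2_sh),
        fld_mean_diff=mean_diff,
        fld_pooled_sigma=sigma,
    )


def fld_fit(X1: np.ndarray, X2: np.ndarray, ridge: float = 0.0) -> FLDModel:
    """Fit the discriminant: S_c = (n_c - 1) cov(X_c), Sw = S1 + S2,
    w* = (Sw + ridge * tr(Sw)/dim * I)^-1 (u1 - u2), Q = Sw / (n1 + n2 - 2)."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("classes must share the neuron set")
    n1, n2 = X1.shape[0], X2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 trials per class")
    u1, u2 = X1.mean(axis=0), X2.mean(axis=0)
    S1 = (n1 - 1) * np.cov(X1, rowvar=False).reshape(X1.shape[1], X1.shape[1])
    S2 = (n2 - 1) * np.cov(X2, rowvar=False).reshape(X2.shape[1], X2.shape[1])
    Sw = S1 + S2
    w_star = _regularized_inverse(Sw, ridge) @ (u1 - u2)
    Q = Sw / (n1 + n2 - 2)
    return FLDModel(w_star=w_star, u1=u1, u2=u2, S1=S1, S2=S2, Sw=Sw, Q=Q, ridge=ridge)


def discriminability(X1: np.ndarray, X2: np.ndarray, ridge: float = 0.0) -> DecoderResult:
    """Fit the FLD on two trial x neuron count matrices and return d2, PCC,
    their correlation-shuffled variants, and the projected mean/SD split."""
    model = fld_fit(X1, X2, ridge=ridge)
    return discriminability_from_moments(model.u1 - model.u2, model.Q, ridge=ridge)


def _evoked_matrices(session: SessionData, subtract_baseline: bool) -> tuple[np.ndarray, np.ndarray]:
    Xt = session.counts["target_evoked"].astype(float)
    Xs = session.counts["test_evoked"].astype(float)
    if subtract_baseline:
        pre = session.counts["pre_test"].astype(float)
        pre_w = session.window_ms["pre_test"]
        Xt = Xt - pre * (session.window_ms["target_evoked"] / pre_w)
        Xs = Xs - pre * (session.window_ms["test_evoked"] / pre_w)
    return Xt, Xs


def state_conditioned_decoding(
    session: SessionData,
    config: AnalysisConfig | None = None,
    state_pool_sizes: tuple[int, ...] | None = None,
) -> list[DecoderResult]:
    """Target-vs-test discriminability of the FULL population, fitted
    separately on low- and high-labeled trials, where the state labels come
    from pooled pre-stimulus activity of m = 1..n neurons (averaged over
    pools at each m).  Pools whose state halves have fewer than dim + 2
    trials are skipped with a warning."""
    config = config or AnalysisConfig()
    n = session.n_neurons
    sizes = state_pool_sizes or tuple(range(1, n + 1))
    pre = window_counts(session, config.alignment, config.window_offset_ms)
    norm = minmax_normalize(pre.astype(float))
    Xt, Xs = _evoked_matrices(session, config.subtract_baseline)
    min_trials = n + 2
    results: list[DecoderResult] = []
    for m in sizes:
        pools = enumerate_pools(n, int(m), cap=config.pool_cap, seed=config.rng_seed)
        acc = {"low": [], "high": []}
        for pool in pools:
            trace = norm[:, list(pool)].mean(axis=1)
            labels = median_split(trace, source_neurons=pool)
            for state, idx in (("low", labels.low_idx()), ("high", labels.high_idx())):
                if idx.size < min_trials:
                    logger.warning(
                        "session %s pool %s: %d %s-state trials < %d; pool skipped",
                        session.session_id, pool, idx.size, state, min_trials,
                    )
                    continue
                acc[state].append(
                    discriminability(Xt[idx], Xs[idx], ridge=config.ridge)
                )
        for state, fits in acc.items():
            if not fits:
                continue
            results.append(
                DecoderResult(
                    d2=float(np.mean([f.d2 for f in fits])),
                    d_prime=float(np.mean([f.d_prime for f in fits])),
                    pcc=float(np.mean([f.pcc for f in fits])),
                    d2_shuffled=float(np.mean([f.d2_shuffled for f in fits])),
                    pcc_shuffled=float(np.mean([f.pcc_shuffled for f in fits])),
                    fld_mean_diff=float(np.mean([f.fld_mean_diff for f in fits])),
                    fld_pooled_sigma=float(np.mean([f.fld_pooled_sigma for f in fits])),
                    state=state,
                    pool_size_for_state=int(m),
                    n_pools_used=len(fits),
                )
            )
    return results


def decoder_table(session_id: str, results: list[DecoderResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.to_row() for r in results])
    df.insert(0, "session_id", session_id)
    return df


def noise_correlations(
    session: SessionData,
    labels: StateLabels,
    min_trials: int = 4,
) -> NoiseCorrResult:
    """Mean pairwise correlation of test-evoked counts per state.

    Counts are z-scored per neuron within each stimulus condition (target
    orientation x delta-theta) so stimulus-driven mean differences do not
    masquerade as correlated noise; per-pair correlations are computed per
    condition and averaged across conditions weighted by trial count.
    Zero-variance neurons within a cell are skipped for that cell.
    """
    if session.n_neurons < 2:
        raise ValueError("noise_correlations needs >= 2 neurons")
    counts = session.counts["test_evoked"].astype(float)
    table = session.trial_table()
    cond = (
        table.target_orientation.astype(str) + "/" + table.delta_theta.astype(str)
    ).to_numpy()
    n_neurons = session.n_neurons
    pairs = [(i, j) for i in range(n_neurons) for j in range(i + 1, n_neurons)]
    out: dict[str, np.ndarray] = {}
    for state, idx in (("low", labels.low_idx()), ("high", labels.high_idx())):
        if idx.size < min_trials:
            raise ValueError(f"{state} state has {idx.size} trials; need >= {min_trials}")
        sums = np.zeros(len(pairs))
        weights = np.zeros(len(pairs))
        for g in pd.unique(cond[idx]):
            sel = idx[cond[idx] == g]
            if sel.size < min_trials:
                continue
            block = counts[sel]
            sd = block.std(axis=0, ddof=1)
            ok = sd > 0
            z = np.zeros_like(block)
            z[:, ok] = (block[:, ok] - block[:, ok].mean(axis=0)) / sd[ok]
            r = (z.T @ z) / (sel.size - 1)
            for p, (i, j) in enumerate(pairs):
                if ok[i] and ok[j]:
                    sums[p] += r[i, j] * sel.size
                    weights[p] += sel.size
        vals = np.where(weights > 0, sums / np.where(weights > 0, weights, 1.0), np.nan)
        out[state] = vals
    both = np.concatenate([out["low"], out["high"]])
    both = both[np.isfinite(both)]
    lo = out["low"][np.isfinite(out["low"])]
    hi = out["high"][np.isfinite(out["high"])]
    return NoiseCorrResult(
        r_sc_low=float(lo.mean()) if lo.size else float("nan"),
        r_sc_high=float(hi.mean()) if hi.size else float("nan"),
        sem_low=float(lo.std(ddof=1) / np.sqrt(lo.size)) if lo.size > 1 else float("nan"),
        sem_high=float(hi.std(ddof=1) / np.sqrt(hi.size)) if hi.size > 1 else float("nan"),
        pair_values_low=out["low"],
        pair_values_high=out["high"],
        fraction_negative=float(np.mean(both < 0)) if both.size else float("nan"),
    )


@dataclass
class MemoryControlResult:
    """Cross-validated decoding of target orientation from pre-test counts."""

    accuracies: np.ndarray  # one per bootstrap iteration
    perm_accuracies: np.ndarray  # label-permutation chance distribution
    mean_accuracy: float
    chance_band: tuple[float, float]  # 2.5/97.5 percentiles of permutations

    @property
    def above_chance(self) -> bool:
        return self.mean_accuracy > self.chance_band[1]


def target_memory_control(
    session: SessionData,
    config: AnalysisConfig | None = None,
    n_boot: int = 100,
    train_frac: float = 0.7,
) -> MemoryControlResult:
    """Linear-discriminant classification of the remembered target
    orientation from the 200-ms pre-test counts of all neurons.

    Each of ``n_boot`` iterations draws a seeded random train/validation
    split (70/30 by default, redrawn if a class is missing from training) and
    reports validation accuracy; a parallel run with permuted labels gives
    the chance band.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    config = config or AnalysisConfig()
    X = session.counts["pre_test"].astype(float)
    y = np.array([t.target_orientation for t in session.trials])
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need >= 2 distinct target orientations")
    rng = np.random.default_rng(config.rng_seed)
    n = len(y)
    n_train = int(round(train_frac * n))

    def _one(y_vec: np.ndarray) -> float:
        for _ in range(100):
            perm = rng.permutation(n)
            tr, va = perm[:n_train], perm[n_train:]
            if np.unique(y_vec[tr]).size == classes.size and va.size:
                break
        else:
            raise RuntimeError("could not draw a split containing every class")
        clf = LinearDiscriminantAnalysis()
        clf.fit(X[tr], y_vec[tr])
        return float(np.mean(clf.predict(X[va]) == y_vec[va]))

    accs = np.array([_one(y) for _ in range(n_boot)])
    perms = np.array([_one(rng.permutation(y)) for _ in range(n_boot)])
    return MemoryControlResult(
        accuracies=accs,
        perm_accuracies=perms,
        mean_accuracy=float(accs.mean()),
        chance_band=(
            float(np.percentile(perms, 2.5)),
            float(np.percentile(perms, 97.5)),
        ),
    )
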