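import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from statepop import (
    AnalysisConfig,
    GeneratorParams,
    MissingEpochError,
    evoked_rates_by_state,
    fano_factor,
    generate_session,
    median_split,
    minmax_normalize,
    state_metrics,
    trial_autocorrelation,
    window_counts,
)
from statepop.state import evoked_fano_by_state

from conftest import make_manual_session


class TestWindowCounts:
    def test_offset_zero_is_the_pre_test_epoch(self, small_session):
        np.testing.assert_array_equal(
            window_counts(small_session, "pre_test", 0),
            small_session.counts["pre_test"],
        )

    def test_missing_offset_raises(self):
        s = generate_session(
            GeneratorParams(n_trials=20, n_neurons=2, store_ladder=False)
        )
        with pytest.raises(MissingEpochError):
            window_counts(s, "pre_test", 400)

    def test_ladder_windows_mutually_independent(self):
        """Each ladder window has its own i.i.d. latent state, so traces from
        different offsets are only weakly correlated."""
        s = generate_session(GeneratorParams(n_trials=1000, n_neurons=8, seed=12))
        traces = {
            off: window_counts(s, "pre_test", off).mean(axis=1)
            for off in (0, 200, 400, 600, 800)
        }
        offs = list(traces)
        for i in range(len(offs)):
            for j in range(i + 1, len(offs)):
                r = np.corrcoef(traces[offs[i]], traces[offs[j]])[0, 1]
                assert abs(r) < 0.1


class TestMinmaxNormalize:
    def test_basic_and_degenerate(self):
        np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])
        np.testing.assert_allclose(minmax_normalize([3, 3, 3]), [0.5, 0.5, 0.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        arrays(
            float,
            st.integers(2, 30),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        )
    )
    def test_idempotent_and_bounded(self, v):
        out = minmax_normalize(v)
        assert np.all((0 <= out) & (out <= 1))
        np.testing.assert_allclose(minmax_normalize(out), out, atol=1e-12)


class TestMedianSplit:
    def test_simple_split(self):
        labels = median_split([1, 5, 2, 8])
        assert list(labels.labels) == ["low", "high", "low", "high"]

    def test_tie_at_median_broken_by_trial_order(self):
        labels = median_split([1, 2, 2, 3])
        assert list(labels.labels) == ["low", "low", "high", "high"]

    def test_exact_balance_at_scale(self):
        rng = np.random.default_rng(0)
        labels = median_split(rng.normal(size=1000))
        assert labels.low_idx().size == labels.high_idx().size == 500

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError):
            median_split([1, 2, 3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        arrays(
            float,
            st.sampled_from([4, 10, 20]),
            elements=st.floats(0, 1e6, allow_nan=False),
            unique=True,
        )
    )
    def test_monotone_invariance(self, v):
        """Rank-based split is unchanged by min-max normalization (tie-free)."""
        np.testing.assert_array_equal(
            median_split(v).high, median_split(minmax_normalize(v)).high
        )


class TestEvokedRatesByState:
    def test_constant_evoked_means_equal(self):
        s = make_manual_session(
            {
                "pre_test": np.arange(8).reshape(8, 1),
                "test_evoked": np.full((8, 1), 6),
            }
        )
        labels = median_split(s.counts["pre_test"][:, 0])
        lo, hi = evoked_rates_by_state(s, labels)
        assert lo[0] == hi[0]

    def test_gain_direction_on_generator(self):
        # sign test across neurons pooled over sessions: evoked rate higher
        # in the high state (single-session splits are too noisy to resolve
        # the direction in every neuron)
        from scipy.stats import binomtest

        diffs = []
        for seed in (42, 43, 44):
            s = generate_session(GeneratorParams(n_trials=800, n_neurons=12,
                                                 seed=seed, store_ladder=False))
            for i in range(s.n_neurons):
                labels = median_split(s.counts["pre_test"][:, i])
                lo, hi = evoked_rates_by_state(s, labels)
                diffs.append(hi[i] - lo[i])
        k = int(np.sum(np.array(diffs) > 0))
        assert binomtest(k, len(diffs), 0.5, alternative="greater").pvalue < 0.01

    def test_baseline_subtraction_cancels_additive_offset(self):
        rng = np.random.default_rng(1)
        pre = rng.poisson(4, size=(40, 2))
        s = make_manual_session(
            {
                "pre_test": pre,
                "test_evoked": pre + 7,
            },
            window_ms={"test_evoked": 200.0},  # same window: rates subtract exactly
        )
        labels = median_split(s.counts["pre_test"][:, 0])
        lo, hi = evoked_rates_by_state(s, labels, subtract_baseline=True)
        np.testing.assert_allclose(lo, hi, atol=1e-9)

    def test_null_gain_no_state_difference(self, null_params):
        from statepop import generate_session

        s = generate_session(null_params)
        diffs = []
        for i in range(s.n_neurons):
            labels = median_split(s.counts["pre_test"][:, i])
            lo, hi = evoked_rates_by_state(s, labels)
            diffs.append(hi[i] - lo[i])
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert abs(diffs.mean()) < 2 * se + 1e-9


class TestFanoFactor:
    def test_constant_counts_zero(self):
        assert fano_factor([4, 4, 4, 4]) == 0.0

    def test_poisson_ff_near_one(self):
        rng = np.random.default_rng(2)
        ff = fano_factor(rng.poisson(10, size=5000))
        assert abs(ff - 1.0) < 0.05

    def test_all_zero_counts_missing(self):
        assert np.isnan(fano_factor([0, 0, 0, 0]))

    def test_within_condition_grouping(self, small_session):
        f_lo, f_hi = evoked_fano_by_state(
            small_session, median_split(small_session.counts["pre_test"][:, 0]), 0
        )
        assert f_lo >= 0 and f_hi >= 0


class TestTrialAutocorrelation:
    def test_lag_zero_is_one_and_alternating_is_minus_one(self):
        v = np.tile([1.0, 0.0], 50)
        ac = trial_autocorrelation(v, max_lag=2)
        assert ac.acf[0] == 1.0
        assert ac.acf[1] == pytest.approx(-1.0)

    def test_white_noise_mostly_within_band(self):
        rng = np.random.default_rng(3)
        ac = trial_autocorrelation(rng.normal(size=500), max_lag=20)
        assert ac.within_band().sum() >= 18

    def test_constant_series_missing(self):
        ac = trial_autocorrelation(np.ones(50), max_lag=3)
        assert np.isnan(ac.acf[1])


def test_state_metrics_table_shape(small_session, config):
    table = state_metrics(small_session, config)
    assert len(table) == small_session.n_neurons
    assert {"pre_rate_mean", "rate_change", "evoked_low", "evoked_high",
            "fano_low", "fano_high"} <= set(table.columns)
    # high-state pre rate exceeds low-state by construction of the split
    assert (table.rate_change > 0).all()
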