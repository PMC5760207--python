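import dataclasses

import numpy as np
import pytest

from statepop import (
    AnalysisConfig,
    GeneratorParams,
    discriminability,
    discriminability_from_moments,
    fld_fit,
    generate_session,
    median_split,
    minmax_normalize,
    noise_correlations,
    pcc_from_d2,
    state_conditioned_decoding,
    target_memory_control,
)

from conftest import make_manual_session


class TestFLDFit:
    def test_scalar_case(self):
        X1 = np.array([[1.0], [3.0]])
        X2 = np.array([[5.0], [7.0]])
        m = fld_fit(X1, X2)
        # 1 neuron: w* = (u1 - u2) / Sw, here (2 - 6) / (2 + 2)
        assert m.w_star[0] == pytest.approx(-1.0)
        assert np.sign(m.w_star[0]) == np.sign(m.u1[0] - m.u2[0])

    def test_identity_covariance_w_parallel_to_mean_diff(self):
        rng = np.random.default_rng(0)
        mu = np.array([2.0, -1.0, 0.5])
        X1 = rng.standard_normal((4000, 3)) + mu
        X2 = rng.standard_normal((4000, 3))
        m = fld_fit(X1, X2)
        cos = m.w_star @ mu / (np.linalg.norm(m.w_star) * np.linalg.norm(mu))
        assert cos > 0.999

    def test_duplicated_neuron_with_ridge(self):
        rng = np.random.default_rng(1)
        X1 = rng.poisson(8.0, size=(300, 3)).astype(float)
        X2 = rng.poisson(5.0, size=(300, 3)).astype(float)
        d_base = discriminability(X1, X2, ridge=0.0).d2
        X1d = np.column_stack([X1, X1[:, 0]])
        X2d = np.column_stack([X2, X2[:, 0]])
        d_dup = discriminability(X1d, X2d, ridge=1e-6).d2
        assert d_dup == pytest.approx(d_base, rel=0.01)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            fld_fit(np.array([[1.0]]), np.array([[2.0], [3.0]]))


class TestDiscriminability:
    def test_closed_form_two_dim(self):
        r = discriminability_from_moments([2.0, 0.0], np.eye(2))
        assert r.d2 == pytest.approx(4.0)
        assert r.pcc == pytest.approx(0.8413447460685429, abs=1e-9)

    def test_hand_inverted_correlated_case(self):
        r = discriminability_from_moments([1.0, 1.0], [[1.0, 0.5], [0.5, 1.0]])
        assert r.d2 == pytest.approx(4.0 / 3.0, abs=1e-12)
        assert r.d2_shuffled == pytest.approx(2.0, abs=1e-12)

    def test_identical_classes(self):
        X = np.random.default_rng(2).poisson(5.0, size=(50, 3)).astype(float)
        r = discriminability(X, X)
        assert r.d2 == 0.0
        assert r.pcc == 0.5
        assert r.d2_shuffled == 0.0

    def test_invariance_under_shared_linear_transform(self):
        rng = np.random.default_rng(3)
        X1 = rng.standard_normal((200, 3)) + [1.0, 0.0, 0.5]
        X2 = rng.standard_normal((200, 3))
        base = discriminability(X1, X2, ridge=0.0).d2
        for _ in range(5):
            A = rng.standard_normal((3, 3))
            d2 = discriminability(X1 @ A.T, X2 @ A.T, ridge=0.0).d2
            assert d2 == pytest.approx(base, abs=1e-8)

    def test_shuffled_equals_d2_for_diagonal_q(self):
        r = discriminability_from_moments([1.0, 2.0], np.diag([2.0, 3.0]))
        assert r.d2_shuffled == pytest.approx(r.d2, abs=1e-12)

    def test_pcc_monotone_with_limits(self):
        d2s = np.linspace(0, 40, 50)
        pccs = [pcc_from_d2(d) for d in d2s]
        assert pccs[0] == 0.5
        assert np.all(np.diff(pccs) > 0)
        assert pccs[-1] > 0.999

    def test_one_dim_equals_classic_d_prime(self):
        rng = np.random.default_rng(4)
        X1 = rng.normal(3.0, 1.5, size=(500, 1))
        X2 = rng.normal(1.0, 1.5, size=(500, 1))
        r = discriminability(X1, X2)
        mu_diff = abs(X1.mean() - X2.mean())
        n1 = n2 = 500
        pooled_var = ((n1 - 1) * X1.var(ddof=1) + (n2 - 1) * X2.var(ddof=1)) / (
            n1 + n2 - 2
        )
        assert np.sqrt(r.d2) == pytest.approx(mu_diff / np.sqrt(pooled_var), abs=1e-10)

    def test_mean_diff_over_sigma_tracks_d_prime(self):
        rng = np.random.default_rng(5)
        X1 = rng.multivariate_normal([1, 0.5], [[1, 0.3], [0.3, 2]], size=2000)
        X2 = rng.multivariate_normal([0, 0], [[1, 0.3], [0.3, 2]], size=2000)
        r = discriminability(X1, X2, ridge=0.0)
        assert r.fld_mean_diff / r.fld_pooled_sigma == pytest.approx(
            np.sqrt(r.d2), abs=1e-10
        )

    def test_closed_form_pcc_matches_empirical_classifier(self):
        """Brute-force oracle: on a 2-neuron Gaussian problem the closed-form
        PCC equals the accuracy of the fitted linear rule on 10^6 samples."""
        rng = np.random.default_rng(6)
        mu1, mu2 = np.array([1.0, 0.5]), np.array([0.0, 0.0])
        Q = np.array([[1.0, 0.3], [0.3, 1.5]])
        L = np.linalg.cholesky(Q)
        n = 1_000_000
        A = rng.standard_normal((n, 2)) @ L.T + mu1
        B = rng.standard_normal((n, 2)) @ L.T + mu2
        r = discriminability_from_moments(mu1 - mu2, Q)
        w = np.linalg.inv(Q) @ (mu1 - mu2)
        b = w @ (mu1 + mu2) / 2
        emp = 0.5 * ((A @ w > b).mean() + (B @ w < b).mean())
        assert abs(r.pcc - emp) < 0.003


class TestStateConditionedDecoding:
    def test_low_state_decodes_better_and_effect_grows_with_pool(self, config):
        lows_win, grows = 0, 0
        n_rep = 15
        for seed in range(n_rep):
            s = generate_session(
                GeneratorParams(n_trials=800, n_neurons=10, seed=seed,
                                store_ladder=False)
            )
            res = state_conditioned_decoding(s, config, state_pool_sizes=(2, 10))
            d = {(r.state, r.pool_size_for_state): r.pcc for r in res}
            lows_win += d[("low", 10)] > d[("high", 10)]
            grows += (d[("low", 10)] - d[("high", 10)]) > (
                d[("low", 2)] - d[("high", 2)]
            )
        assert lows_win >= 0.9 * n_rep
        assert grows >= 0.6 * n_rep

    def test_state_blind_generator_no_pcc_difference(self, null_params, config):
        diffs = []
        for seed in range(15):
            s = generate_session(dataclasses.replace(null_params, seed=seed,
                                                     n_trials=600, n_neurons=8,
                                                     store_ladder=False))
            res = state_conditioned_decoding(s, config, state_pool_sizes=(8,))
            d = {r.state: r.pcc for r in res}
            diffs.append(d["low"] - d["high"])
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert abs(diffs.mean()) < 2 * se + 1e-9

    def test_baseline_subtraction_collapses_state_difference(self, config):
        """When evoked responses are ongoing activity plus an orientation
        signal, subtracting the pre-stimulus counts removes the state
        dependence of decoding."""
        rng = np.random.default_rng(7)
        n, m = 600, 6
        s_t = rng.standard_normal(n)
        lam = 4.0 * np.exp(0.8 * s_t)[:, None] * np.ones((1, m))
        pre = rng.poisson(lam)
        sigA = rng.poisson(6.0, size=(n, m))
        sigB = rng.poisson(3.0, size=(n, m))
        sess = make_manual_session(
            {
                "pre_test": pre,
                "target_evoked": pre + sigA,
                "test_evoked": pre + sigB,
            },
            window_ms={"target_evoked": 200.0, "test_evoked": 200.0},
        )

        def diff(cfg):
            res = state_conditioned_decoding(sess, cfg, state_pool_sizes=(m,))
            d = {r.state: r.pcc for r in res}
            return d["low"] - d["high"]

        raw = diff(config)
        sub = diff(dataclasses.replace(config, subtract_baseline=True))
        assert abs(sub) < abs(raw)
        assert abs(sub) < 0.02


class TestNoiseCorrelations:
    def test_duplicated_neuron_perfect_correlation(self):
        rng = np.random.default_rng(8)
        base = rng.poisson(6.0, size=(80, 1))
        sess = make_manual_session(
            {"test_evoked": np.column_stack([base, base]),
             "pre_test": rng.poisson(4.0, size=(80, 2))}
        )
        labels = median_split(sess.counts["pre_test"][:, 0])
        nc = noise_correlations(sess, labels)
        assert nc.r_sc_low == pytest.approx(1.0)
        assert nc.r_sc_high == pytest.approx(1.0)

    def test_independent_poisson_near_zero(self):
        s = generate_session(
            GeneratorParams(n_trials=2000, n_neurons=12, state_sd=0.0,
                            shared_noise_lowhigh=(0.0, 0.0), evoked_gain_slope=0.0,
                            seed=9, store_ladder=False)
        )
        trace = minmax_normalize(s.counts["pre_test"].astype(float)).mean(axis=1)
        nc = noise_correlations(s, median_split(trace))
        assert abs((nc.r_sc_low + nc.r_sc_high) / 2) < 0.01

    def test_shared_noise_raises_high_state_correlations(self):
        from scipy.stats import wilcoxon

        s = generate_session(
            GeneratorParams(n_trials=2000, n_neurons=10, seed=10, store_ladder=False)
        )
        trace = minmax_normalize(s.counts["pre_test"].astype(float)).mean(axis=1)
        nc = noise_correlations(s, median_split(trace))
        ok = np.isfinite(nc.pair_values_low) & np.isfinite(nc.pair_values_high)
        p = wilcoxon(nc.pair_values_high[ok], nc.pair_values_low[ok],
                     alternative="greater").pvalue
        assert p < 0.01


class TestTargetMemoryControl:
    def test_no_leak_within_chance_band(self, config):
        s = generate_session(GeneratorParams(n_trials=400, n_neurons=8, seed=11,
                                             store_ladder=False))
        mc = target_memory_control(s, config, n_boot=40)
        assert mc.chance_band[0] <= mc.mean_accuracy <= mc.chance_band[1] + 0.02
        assert not mc.above_chance or mc.mean_accuracy < mc.chance_band[1] + 0.02

    def test_large_leak_detected(self, config):
        s = generate_session(
            GeneratorParams(n_trials=400, n_neurons=8, memory_leak=0.8, seed=12,
                            baseline_rate=30.0, store_ladder=False)
        )
        mc = target_memory_control(s, config, n_boot=40)
        assert mc.above_chance

    def test_fixed_seed_reproducible(self, config):
        s = generate_session(GeneratorParams(n_trials=200, n_neurons=5, seed=13,
                                             store_ladder=False))
        a = target_memory_control(s, config, n_boot=10)
        b = target_memory_control(s, config, n_boot=10)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
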