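import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cgmchaos as cc
from cgmchaos.chaos_analysis import (
    EmbeddingSpec,
    average_mutual_information,
    cao_embedding_dimension,
    correlation_sum,
    denoise_phase,
    denoise_radius_for_dimension,
    embed,
    lyapunov_exponent,
    reconstruct_series,
    recurrence_matrix,
    select_delay_acf,
)


class TestAverageMutualInformation:
    def test_iid_noise_profile_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10000)
        profile, tau = average_mutual_information(x, max_lag=10)
        # estimator bias bound from a shuffled surrogate of the same series
        shuffled = rng.permutation(x)
        surr, _ = average_mutual_information(shuffled, max_lag=10)
        bias = surr[1:].max() * 3 + 0.02
        assert (profile[1:] < bias).all()
        assert tau == 1

    def test_lag_zero_equals_histogram_entropy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=5000)
        profile, _ = average_mutual_information(x, max_lag=5, bins=16)
        counts, _ = np.histogram(x, bins=16)
        p = counts / counts.sum()
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert profile[0] == pytest.approx(entropy, rel=1e-9)
        assert profile[0] == profile.max()

    def test_periodic_series_recovers_entropy_at_period(self):
        rng = np.random.default_rng(3)
        x = np.tile(rng.normal(size=7), 300)
        profile, _ = average_mutual_information(x, max_lag=10, bins=8)
        assert profile[7] == pytest.approx(profile[0], rel=1e-9)

    def test_affine_invariance_with_fixed_bins(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=4000)
        a, _ = average_mutual_information(x, max_lag=8, bins=12)
        b, _ = average_mutual_information(3.5 * x - 40.0, max_lag=8, bins=12)
        assert np.allclose(a, b)

    def test_constant_series_warns_and_defaults(self):
        with pytest.warns(UserWarning):
            profile, tau = average_mutual_information(np.full(200, 5.0), max_lag=5)
        assert tau == 1
        assert (profile == 0).all()


class TestSelectDelayAcf:
    @pytest.mark.parametrize("phi, expected", [(0.5, 2), (0.9, 10)])
    def test_ar1_first_crossing_of_1_over_e(self, phi, expected):
        rng = np.random.default_rng(11)
        e = rng.standard_normal(200000)
        x = np.empty_like(e)
        x[0] = 0.0
        for i in range(1, len(e)):
            x[i] = phi * x[i - 1] + e[i]
        assert select_delay_acf(x, max_lag=30) == expected

    def test_iid_noise_gives_lag_one(self):
        rng = np.random.default_rng(12)
        assert select_delay_acf(rng.normal(size=5000), max_lag=20) == 1

    def test_no_crossing_warns_and_returns_max(self):
        x = np.linspace(0, 1, 500)  # near-perfectly autocorrelated ramp
        with pytest.warns(UserWarning):
            assert select_delay_acf(x, max_lag=5) == 5


class TestCaoEmbedding:
    def test_sine_embeds_in_two_dimensions(self):
        # quarter-period delay of an (incommensurate-period) sine: a circle
        x = np.sin(2 * np.pi * np.arange(4000) / 40.7)
        m, _ = cao_embedding_dimension(x, tau=10, m_max=6)
        assert m == 2

    def test_henon_needs_two_dimensions(self, henon_series):
        m, e1 = cao_embedding_dimension(henon_series, tau=1, m_max=8)
        assert m == 2
        assert e1[0] < 0.5  # one dimension is clearly insufficient

    def test_white_noise_returns_m_max_with_warning(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="noise-like"):
            m, _ = cao_embedding_dimension(rng.normal(size=3000), tau=1, m_max=7)
        assert m == 7

    def test_insufficient_length_rejected(self):
        with pytest.raises(ValueError):
            cao_embedding_dimension(np.arange(30.0), tau=5, m_max=8)


class TestEmbedReconstruct:
    def test_documented_example(self):
        pm = embed([1, 2, 3, 4, 5, 6], EmbeddingSpec(m=2, tau=2))
        assert pm.data.tolist() == [[1, 3], [2, 4], [3, 5], [4, 6]]
        assert pm.n_vectors == 4

    def test_m1_is_identity_column(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        pm = embed(x, EmbeddingSpec(m=1, tau=1))
        assert pm.data.shape == (5, 1)
        assert np.array_equal(reconstruct_series(pm), x)

    def test_too_short_series_names_minimum(self):
        with pytest.raises(ValueError, match="7"):
            embed(np.arange(5.0), EmbeddingSpec(m=3, tau=3))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        n=st.integers(8, 60),
        m=st.integers(1, 5),
        tau=st.integers(1, 4),
        seed=st.integers(0, 10_000),
    )
    def test_round_trip_identity(self, n, m, tau, seed):
        if n < m * tau + 1:
            return
        x = np.random.default_rng(seed).normal(size=n)
        pm = embed(x, EmbeddingSpec(m=m, tau=tau))
        assert np.array_equal(reconstruct_series(pm), x)

    def test_reconstruction_length(self):
        x = np.random.default_rng(0).normal(size=40)
        pm = embed(x, EmbeddingSpec(m=4, tau=3))
        assert pm.n_vectors == 40 - 9
        assert len(reconstruct_series(pm)) == pm.n_vectors + 9


class TestDenoise:
    def test_radius_zero_is_identity(self):
        x = np.random.default_rng(1).normal(size=100)
        assert np.array_equal(denoise_phase(x, m=3, radius=0.0), x)

    def test_constant_series_unchanged(self):
        x = np.full(50, 2.5)
        assert np.allclose(denoise_phase(x, m=3, radius=1.0), x)

    def test_averaging_respects_cluster_separation(self):
        # two well-separated plateaus: averaging must stay within each
        x = np.concatenate([np.zeros(30), np.full(30, 100.0)])
        out = denoise_phase(x, m=2, radius=1.0)
        # brute-force oracle: each delay vector's neighbours within radius
        from cgmchaos.chaos_analysis import _delay_matrix

        Y = _delay_matrix(x, 2, 1)
        expected_vec = np.empty_like(Y)
        for i in range(len(Y)):
            d = np.sqrt(((Y - Y[i]) ** 2).sum(axis=1))
            expected_vec[i] = Y[d <= 1.0].mean(axis=0)
        acc = np.zeros(len(x))
        cnt = np.zeros(len(x))
        for j in range(2):
            acc[j : j + len(Y)] += expected_vec[:, j]
            cnt[j : j + len(Y)] += 1
        assert np.allclose(out, acc / cnt)
        assert set(np.round(out, 6)) <= {0.0, 50.0, 100.0}

    def test_variance_contraction(self):
        x = np.random.default_rng(2).normal(size=400)
        out = denoise_phase(x, m=3, radius=0.5)
        assert out.var() <= x.var()

    def test_radius_schedule_endpoints(self):
        assert denoise_radius_for_dimension(2) == 0.2
        assert denoise_radius_for_dimension(10) == pytest.approx(1e-4)
        mid = denoise_radius_for_dimension(6)
        assert 1e-4 < mid < 0.2


class TestLyapunov:
    def test_periodic_signal_has_no_divergence(self):
        x = np.sin(2 * np.pi * np.arange(3000) / 40.7)
        lam = lyapunov_exponent(x, EmbeddingSpec(m=2, tau=10))
        assert lam <= 0.02

    def test_henon_exponent(self, henon_series):
        lam = lyapunov_exponent(henon_series, EmbeddingSpec(m=2, tau=1))
        assert lam == pytest.approx(0.42, abs=0.08)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            lyapunov_exponent(np.arange(12.0), EmbeddingSpec(m=3, tau=2))


class TestCorrelationDimension:
    def test_monotone_ramp_is_one_dimensional(self):
        d2, _ = cc.correlation_dimension(
            np.linspace(0, 1, 2000), EmbeddingSpec(m=2, tau=1)
        )
        assert d2 == pytest.approx(1.0, abs=0.1)

    def test_correlation_sum_matches_brute_force(self):
        rng = np.random.default_rng(3)
        Y = rng.random((120, 2))
        radii = np.array([0.05, 0.2, 0.5])
        C = correlation_sum(Y, radii, theiler=2)
        # independent O(n^2) loop
        hits = np.zeros(3)
        total = 0
        for i in range(len(Y)):
            for j in range(i + 3, len(Y)):
                d = np.hypot(*(Y[i] - Y[j]))
                total += 1
                hits += d <= radii
        assert np.allclose(C, hits / total)


class TestRecurrence:
    def test_matrix_symmetric_with_unit_diagonal(self):
        x = np.random.default_rng(4).normal(size=120)
        R = recurrence_matrix(x, EmbeddingSpec(m=2, tau=1), cutoff=0.5)
        assert np.array_equal(R, R.T)
        assert (np.diag(R) == 1).all()

    def test_cutoff_beyond_diameter_gives_all_ones(self):
        x = np.random.default_rng(5).normal(size=60)
        R = recurrence_matrix(x, EmbeddingSpec(m=2, tau=1), cutoff=1e6)
        assert (R == 1).all()

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            recurrence_matrix(np.arange(10.0), EmbeddingSpec(m=1, tau=1), cutoff=0.0)
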