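"""Generator tests: waiting-time law, renewal trains, fGn, subordination."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

import mdea
from mdea import FbmParams, RenewalParams


def ipl_cdf(tau, mu, T):
    return 1.0 - (T / (T + tau)) ** (mu - 1.0)


# ---------------------------------------------------------------------------
# Waiting times
# ---------------------------------------------------------------------------

class TestWaitingTime:
    @pytest.mark.parametrize("mu,T,u,expected", [
        (2.0, 1.0, 0.5, 1.0),
        (3.0, 2.0, 0.25, 2.0),
    ])
    def test_closed_form_examples(self, mu, T, u, expected):
        assert mdea.sample_waiting_time(mu, T, u) == pytest.approx(expected)

    def test_matches_numerical_cdf_inversion(self):
        # Independent oracle: invert the CDF by bracketed root finding.
        mu, T, u = 1.5, 1.0, 0.81
        tau_oracle = optimize.brentq(
            lambda t: ipl_cdf(t, mu, T) - (1.0 - u), 0.0, 1e6)
        tau = mdea.sample_waiting_time(mu, T, u)
        assert tau == pytest.approx(tau_oracle, rel=1e-9)
        assert tau == pytest.approx(0.52416, abs=1e-4)

    @pytest.mark.parametrize("bad", [
        dict(mu=1.0, T=1.0, u=0.5),
        dict(mu=2.0, T=0.0, u=0.5),
        dict(mu=2.0, T=1.0, u=0.0),
        dict(mu=2.0, T=1.0, u=1.0),
    ])
    def test_invalid_parameters_raise(self, bad):
        with pytest.raises(ValueError):
            mdea.sample_waiting_time(**bad)

    @pytest.mark.parametrize("mu,T", [(1.5, 1.0), (2.5, 1.0), (2.0, 2.0)])
    def test_ks_against_analytic_cdf(self, mu, T):
        rng = np.random.default_rng(42)
        u = np.clip(rng.random(10_000), 1e-12, 1 - 1e-12)
        taus = mdea.sample_waiting_time(mu, T, u)
        res = stats.kstest(taus, lambda t: ipl_cdf(t, mu, T))
        assert res.pvalue > 0.01

    @pytest.mark.parametrize("mu", [1.5, 2.5])
    def test_survival_tail_exponent(self, mu):
        T = 1.0
        rng = np.random.default_rng(7)
        u = np.clip(rng.random(1_000_000), 1e-15, 1 - 1e-15)
        taus = np.sort(mdea.sample_waiting_time(mu, T, u))
        grid = np.logspace(1, 3, 12) * T
        surv = 1.0 - np.searchsorted(taus, grid) / taus.size
        fit = stats.linregress(np.log(grid), np.log(surv))
        assert fit.slope == pytest.approx(-(mu - 1.0), abs=0.1)

    @given(mu=st.floats(1.1, 2.9), T=st.floats(0.1, 10.0),
           u=st.floats(0.001, 0.999))
    @settings(max_examples=100, deadline=None)
    def test_survival_roundtrip(self, mu, T, u):
        tau = mdea.sample_waiting_time(mu, T, u)
        assert tau > 0
        assert (T / (T + tau)) ** (mu - 1.0) == pytest.approx(u, rel=1e-9)


# ---------------------------------------------------------------------------
# Event trains
# ---------------------------------------------------------------------------

class TestEventTrain:
    def test_empty_train_when_no_event_fits(self):
        # First waiting time of order T=1e6 cannot land inside 10 ticks.
        train = mdea.generate_event_train(
            RenewalParams(mu=3.0, T=1e6, length=10, seed=0))
        assert train.n_events == 0

    def test_strictly_increasing_and_bounded(self):
        train = mdea.generate_event_train(
            RenewalParams(mu=2.5, T=1.0, length=50_000, seed=3))
        assert np.all(np.diff(train.times) >= 1)
        assert train.times[0] >= 0 and train.times[-1] < 50_000

    def test_mean_gap_matches_theory(self):
        # <tau> = T / (mu - 2) for mu > 2.
        train = mdea.generate_event_train(
            RenewalParams(mu=2.5, T=1.0, length=1_000_000, seed=11))
        gaps = np.diff(train.times)
        se = gaps.std() / np.sqrt(gaps.size)
        assert abs(gaps.mean() - 2.0) < 3 * se

    def test_deterministic_under_seed(self):
        p = RenewalParams(mu=2.5, T=1.0, length=10_000, seed=5)
        a = mdea.generate_event_train(p)
        b = mdea.generate_event_train(p)
        np.testing.assert_array_equal(a.times, b.times)


class TestCoinTossFilling:
    def test_piecewise_constant_on_laminar_regions(self):
        train = mdea.EventTrain(times=np.array([3, 7]), length=10)
        s = mdea.fill_laminar_coin_toss(train, W=1.0, seed=1)
        v = s.values
        assert len(set(v[:3])) == 1
        assert len(set(v[3:7])) == 1
        assert len(set(v[7:])) == 1
        assert set(np.unique(v)) <= {1.0, -1.0}

    def test_amplitude_respected(self):
        train = mdea.EventTrain(times=np.array([5]), length=20)
        s = mdea.fill_laminar_coin_toss(train, W=2.5, seed=0)
        assert set(np.unique(np.abs(s.values))) == {2.5}

    def test_fair_coin_flip_fraction(self, fixtures):
        train = fixtures["train_mu2.5_1e4"]
        s = mdea.fill_laminar_coin_toss(train, W=1.0, seed=9)
        region_signs = np.concatenate(
            ([s.values[0]], s.values[train.times]))
        flips = np.mean(np.diff(region_signs) != 0)
        n = region_signs.size - 1
        assert abs(flips - 0.5) < 3 * np.sqrt(0.25 / n)


# ---------------------------------------------------------------------------
# Fractional Gaussian noise
# ---------------------------------------------------------------------------

class TestFgn:
    def test_h_half_is_white(self):
        x = mdea.generate_fgn(FbmParams(H=0.5, length=200_000, seed=1)).values
        lag1 = np.mean(x[:-1] * x[1:])
        assert abs(lag1) < 3.0 / np.sqrt(x.size)

    def test_lag1_autocovariance_h075(self):
        # gamma(1) = (2^(2H) - 2)/2 = sqrt(2) - 1 at H = 0.75.
        x = mdea.generate_fgn(FbmParams(H=0.75, length=400_000, seed=2)).values
        lag1 = np.mean(x[:-1] * x[1:])
        assert lag1 == pytest.approx(np.sqrt(2) - 1, abs=0.02)

    @pytest.mark.parametrize("H", [0.3, 0.6, 0.8])
    def test_autocovariance_lags_0_to_5(self, H):
        # Oracle written out independently of the generator's helper.
        x = mdea.generate_fgn(FbmParams(H=H, length=500_000, seed=4)).values
        for k in range(6):
            exact = 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H)
                           + abs(k - 1) ** (2 * H))
            emp = np.mean(x[: x.size - k] * x[k:])
            assert emp == pytest.approx(exact, abs=0.02)

    def test_partial_sum_variance_scaling(self):
        # Ensemble <X^2(n)> ~ n^(2H): log-log slope 1.2 +/- 0.05 at H=0.6.
        n, R = 1000, 1000
        X2 = np.zeros(n)
        for i in range(R):
            v = mdea.generate_fgn(FbmParams(H=0.6, length=n,
                                            seed=70_000 + i)).values
            X2 += np.cumsum(v) ** 2
        X2 /= R
        g = np.array([10, 30, 100, 300, 1000])
        fit = stats.linregress(np.log(g), np.log(X2[g - 1]))
        assert fit.slope == pytest.approx(1.2, abs=0.05)

    @pytest.mark.parametrize("H", [0.3, 0.7])
    def test_circulant_and_mandelbrot_vanness_agree(self, H):
        # Two-sample KS on the marginal and on a lag-1 pair statistic.
        R, n, idx = 1000, 256, 100
        a = np.empty((R, 2))
        b = np.empty((R, 2))
        for i in range(R):
            x = mdea.generate_fgn(FbmParams(H=H, length=n,
                                            seed=3000 + i)).values
            y = mdea.generate_fgn(FbmParams(H=H, length=n, seed=9000 + i,
                                            method="mandelbrot_vanness")).values
            a[i] = x[idx], x[idx] * x[idx + 1]
            b[i] = y[idx], y[idx] * y[idx + 1]
        assert stats.ks_2samp(a[:, 0], b[:, 0]).pvalue > 0.01
        assert stats.ks_2samp(a[:, 1], b[:, 1]).pvalue > 0.01

    def test_invalid_hurst_raises(self):
        with pytest.raises(ValueError):
            FbmParams(H=1.2, length=10)
        with pytest.raises(ValueError):
            FbmParams(H=0.0, length=10)

    def test_bit_reproducible(self):
        for method in ("circulant", "mandelbrot_vanness", "spectral"):
            p = FbmParams(H=0.6, length=2048, seed=8, method=method)
            np.testing.assert_array_equal(mdea.generate_fgn(p).values,
                                          mdea.generate_fgn(p).values)


class TestSpectralGenerator:
    def test_zero_modes_gives_zero_series(self):
        s = mdea.generate_fgn_spectral(FbmParams(H=0.6, length=100, seed=0),
                                       n_modes=0)
        assert np.all(s.values == 0)

    def test_eta_corresponds_to_hurst(self):
        # eta = 2 - 2H, so H = 1 - eta/2: eta = 0.8 <-> H = 0.6.
        H = 1.0 - 0.8 / 2.0
        assert H == pytest.approx(0.6)
        s = mdea.generate_fgn_spectral(FbmParams(H=H, length=4096, seed=3),
                                       n_modes=500)
        assert np.var(s.values) == pytest.approx(1.0, abs=0.25)

    def test_ensemble_autocorrelation_decay(self):
        # E[acf(t)] ~ t^(-eta) with eta = 0.8 inside the band-limited
        # regime; wide explicit band keeps the low-frequency cutoff from
        # contaminating lags up to 100.
        R, M, n = 1000, 400, 2048
        acf = np.zeros(n)
        for i in range(R):
            v = mdea.generate_fgn_spectral(
                FbmParams(H=0.6, length=n, seed=i), n_modes=M,
                band=(1e-5, np.pi)).values
            f = np.fft.rfft(v, 2 * n)
            acf += np.fft.irfft(f * np.conj(f))[:n] / n
        acf /= R
        lags = np.unique(np.round(np.logspace(1, 2, 12)).astype(int))
        vals = acf[lags] / acf[0]
        assert np.all(vals > 0)
        fit = stats.linregress(np.log(lags), np.log(vals))
        assert fit.slope == pytest.approx(-0.8, abs=0.1)


# ---------------------------------------------------------------------------
# Subordination
# ---------------------------------------------------------------------------

class TestSubordination:
    def test_structure_and_conservation(self):
        train = mdea.EventTrain(times=np.array([2, 5]), length=8)
        incs = mdea.FluctuationSeries(values=np.array([1.5, -2.0, 3.0]))
        out = mdea.subordinate(incs, train)
        expected = np.zeros(8)
        expected[2], expected[5] = 1.5, -2.0
        np.testing.assert_array_equal(out.values, expected)
        assert out.values.sum() == pytest.approx(incs.values[:2].sum())

    def test_more_events_than_increments_raises(self):
        train = mdea.EventTrain(times=np.array([0, 1, 2]), length=5)
        incs = mdea.FluctuationSeries(values=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            mdea.subordinate(incs, train)

    def test_symmetric_ctrw_ensemble_scaling(self):
        """Ensemble entropy of X(l) for iid Gaussian steps at crucial
        times grows with slope (mu-1)/2 = 0.4 for mu = 1.8."""
        R, lmax = 1500, 10_000
        ls = np.array([100, 300, 1000, 3000, 10_000])
        Y = {l: np.empty(R) for l in ls}
        for i in range(R):
            tr = mdea.generate_event_train(
                RenewalParams(mu=1.8, T=1.0, length=lmax, seed=50_000 + i))
            X = np.zeros(lmax)
            if tr.n_events:
                inc = np.random.default_rng(90_000 + i).standard_normal(
                    tr.n_events)
                X[tr.times] = inc
                X = np.cumsum(X)
            for l in ls:
                Y[l][i] = X[l - 1]
        Ss = []
        for l in ls:
            y = Y[l]
            width = np.subtract(*np.percentile(y, [75, 25])) or 1.0
            d = width / 20
            Ss.append(mdea.empirical_entropy(y, d) + np.log(d))
        fit = stats.linregress(np.log(ls), Ss)
        assert fit.slope == pytest.approx(0.4, abs=0.05)

    def test_combined_series_deterministic(self):
        a = mdea.combined_series(mu=2.5, H=0.7, length=20_000, seed=4)
        b = mdea.combined_series(mu=2.5, H=0.7, length=20_000, seed=4)
        np.testing.assert_array_equal(a.values, b.values)
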