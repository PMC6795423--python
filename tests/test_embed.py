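import numpy as np
import pytest

from lfpattr.dataio import Trial
from lfpattr.embed import (
    NoCrossingError,
    ami_lag,
    autocorr_lag,
    average_mutual_information,
    embed_delay,
    fnn_curve,
    lag_distribution,
    min_embedding_dim,
)
from lfpattr.synthio import GeneratorConfig, generate_trial_set
from tests.conftest import make_trialset


def autocorr_oracle(x, max_lag):
    """Direct O(N^2) biased autocorrelation, lags 0..max_lag."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    n = x.size
    return np.array(
        [np.sum(xc[: n - k] * xc[k:]) / n for k in range(max_lag + 1)]
    ) / (np.sum(xc * xc) / n)


class TestAutocorrLag:
    def test_sine_quarter_period(self):
        t = np.arange(20000) / 10_000.0
        trial = Trial(np.sin(2 * np.pi * 5 * t), rate=10_000.0)
        est = autocorr_lag(trial)
        # analytic zero of the cosine autocorrelation is T/4 = 500
        # samples; the finite-window boundary term of the biased linear
        # estimator shifts the crossing by ~1%
        assert 500 <= est.lag_samples <= 508
        assert est.lag_seconds == est.lag_samples / 10_000.0

    @pytest.mark.parametrize("seed", range(5))
    def test_white_noise_decorrelates_immediately(self, seed):
        x = np.random.default_rng(seed).normal(size=10_000)
        lags = autocorr_lag(Trial(x, rate=1000.0)).lag_samples
        assert lags <= 3  # first sign change essentially at lag 1

    def test_two_tone_matches_direct_oracle(self):
        t = np.arange(2000) / 1000.0
        x = np.cos(2 * np.pi * 3 * t) + 0.7 * np.cos(2 * np.pi * 4.7 * t + 0.5)
        est = autocorr_lag(Trial(x, rate=1000.0))
        rho = autocorr_oracle(x, 1000)
        oracle_n = int(np.nonzero(rho[1:] <= 1e-10)[0][0]) + 1
        assert est.lag_samples == oracle_n

    def test_fft_equals_direct_autocorrelation(self, rng):
        from lfpattr.embed import autocorrelation
        x = rng.normal(size=600)
        np.testing.assert_allclose(
            autocorrelation(x, 200), autocorr_oracle(x, 200), atol=1e-10
        )

    def test_no_crossing_raises(self):
        # a horizon shorter than the first zero crossing must be reported
        t = np.arange(20000) / 10_000.0
        trial = Trial(np.sin(2 * np.pi * 5 * t), rate=10_000.0)
        with pytest.raises(NoCrossingError):
            autocorr_lag(trial, max_lag=300)


class TestAMI:
    def test_independent_samples_have_near_zero_ami(self, rng):
        x = rng.normal(size=40_000)
        shuffled = rng.permutation(x)
        mi = average_mutual_information(shuffled, lag=17, bins=16)
        assert mi < 2.0 / 16**2  # plug-in bias bound for independent pairs

    @staticmethod
    def naive_mi(x, lag, bins):
        """Independent MI oracle: quantile binning + histogram2d."""
        edges = np.quantile(x, np.linspace(0, 1, bins + 1))
        edges[0] -= 1e-9
        edges[-1] += 1e-9
        h, _, _ = np.histogram2d(x[:-lag], x[lag:], bins=[edges, edges])
        p = h / h.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        nz = p > 0
        return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))

    def test_first_minimum_matches_dense_oracle(self):
        # the returned lag is the first minimum of the dense AMI curve
        # that is prominent beyond the plug-in bias scale, checked
        # against an independent histogram2d-based MI evaluation
        t = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 2 * t)
        est = ami_lag(Trial(x, rate=1000.0), bins=16)
        mis = [self.naive_mi(x, lag, 16) for lag in range(1, 200)]
        tol = 15**2 / (2.0 * (x.size - 1))
        best, best_lag = mis[0], 1
        oracle = None
        for lag in range(2, 200):
            cur = mis[lag - 1]
            if cur < best:
                best, best_lag = cur, lag
            elif cur > best + tol:
                oracle = best_lag
                break
        assert est.lag_samples == oracle

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=3000).cumsum()
        a = ami_lag(Trial(x - x.min() + 1, rate=1000.0))
        b = ami_lag(Trial(np.log(x - x.min() + 1), rate=1000.0))
        assert a.lag_samples == b.lag_samples

    @pytest.mark.parametrize("seed", [0, 3, 5])
    def test_generator_default_ami_shorter_than_autocorr_lag(self, seed):
        # on the smooth two-tone surrogate the AMI minimum sits at
        # roughly half the autocorrelation lag (real recordings, with
        # their broadband fine structure, separate the two much further)
        cfg = GeneratorConfig(n_trials=1, seed=seed)
        from lfpattr.dataio import trim_transient
        trial = trim_transient(generate_trial_set(cfg))[0]
        ac = autocorr_lag(trial)
        am = ami_lag(trial)
        assert am.lag_samples < 0.8 * ac.lag_samples


class TestEmbedDelay:
    def test_direct_application(self):
        traj = embed_delay(np.array([1.0, 2, 3, 4, 5]), d=2, lag=2)
        np.testing.assert_array_equal(
            traj.points, [[1, 3], [2, 4], [3, 5]]
        )

    def test_d1_is_identity(self, rng):
        x = rng.normal(size=50)
        traj = embed_delay(x, d=1, lag=7)
        np.testing.assert_array_equal(traj.points[:, 0], x)

    def test_point_count_contract(self):
        x = np.zeros(15000)
        traj = embed_delay(x, d=3, lag=1953)
        assert len(traj) == 15000 - 2 * 1953  # = 11094

    def test_coordinates_reproduce_source_exactly(self, rng):
        x = rng.normal(size=200)
        traj = embed_delay(x, d=4, lag=13)
        for j in range(4):
            np.testing.assert_array_equal(
                traj.points[:, j], x[13 * j : 13 * j + len(traj)]
            )

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            embed_delay(np.zeros(10), d=3, lag=5)


class TestFNN:
    def test_pure_sine_is_planar(self):
        t = np.arange(5000) / 1000.0
        x = np.sin(2 * np.pi * 3 * t)
        curve = fnn_curve(x, lag=83, f=12.0, theiler=100, d_max=3)
        assert curve.fnn_percent[0] > 1.0    # a line segment folds badly
        assert curve.fnn_percent[1] < 0.1    # the circle embeds in the plane

    def test_fnn_non_increasing_on_noiseless_signals(self):
        t = np.arange(8000) / 1000.0
        x = np.cos(2 * np.pi * 2 * t) + 0.4 * np.cos(2 * np.pi * 5.5 * t + 0.9)
        curve = fnn_curve(x, lag=120, f=12.0, theiler=100, d_max=4)
        assert np.all(np.diff(curve.fnn_percent) <= 1e-9)

    def test_dmax_one_returns_single_entry(self):
        x = np.sin(np.arange(3000) / 30.0)
        curve = fnn_curve(x, lag=40, f=12.0, theiler=50, d_max=1)
        assert curve.dims.tolist() == [1]
        assert curve.fnn_percent.size == 1


class TestMinEmbeddingDim:
    def test_first_dim_under_threshold(self):
        from lfpattr.embed import FNNCurve
        curve = FNNCurve(
            dims=np.arange(1, 5), fnn_percent=np.array([40.0, 5.0, 0.05, 0.0]),
            f=12.0, theiler=500, tau=100,
        )
        assert min_embedding_dim(curve, 0.1) == 3

    def test_error_when_never_attained(self):
        from lfpattr.embed import FNNCurve
        curve = FNNCurve(
            dims=np.arange(1, 4), fnn_percent=np.array([40.0, 5.0, 1.0]),
            f=12.0, theiler=500, tau=100,
        )
        with pytest.raises(ValueError):
            min_embedding_dim(curve, 0.1)


class TestLagDistribution:
    def test_weighted_mean_of_known_lags(self):
        # two trials decorrelating at 0.1 s and two at 0.3 s average to 0.2 s
        t = np.arange(2000) / 1000.0
        slow = np.sin(2 * np.pi * (1 / 1.2) * t)   # quarter period 0.3 s
        fast = np.sin(2 * np.pi * 2.5 * t)         # quarter period 0.1 s
        tset = make_trialset([fast, fast, slow, slow])
        dist = lag_distribution(tset, method="autocorr")
        assert dist.weighted_mean == pytest.approx(0.2, rel=0.02)
        assert min(dist.lag_seconds) <= dist.weighted_mean <= max(dist.lag_seconds)

    def test_single_trial(self):
        t = np.arange(2000) / 1000.0
        tset = make_trialset([np.sin(2 * np.pi * 2.5 * t)])
        dist = lag_distribution(tset)
        assert dist.weighted_mean == dist.per_trial[0].lag_seconds

    def test_faulty_trials_are_screened(self, rng):
        t = np.arange(2000) / 1000.0
        good = np.sin(2 * np.pi * 2.5 * t)
        faulty = 0.005 * rng.normal(size=2000)  # peak-to-peak well below 0.04
        tset = make_trialset([good, faulty, good])
        dist = lag_distribution(tset)
        assert dist.excluded_faulty == [2]
        assert len(dist.per_trial) == 2

    def test_all_faulty_raises(self, rng):
        tset = make_trialset(0.001 * rng.normal(size=(3, 500)))
        with pytest.raises(ValueError):
            lag_distribution(tset)

    def test_histogram_counts_cover_valid_trials(self, small_quasiperiodic_set):
        dist = lag_distribution(small_quasiperiodic_set)
        assert dist.counts.sum() == len(dist.per_trial)
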