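import itertools

import numpy as np
import pytest

from lfpattr.compare import (
    discrete_frechet,
    frechet_block,
    ks_matrix,
    percent_change,
)
from lfpattr.embed import autocorr_lag
from lfpattr.synthio import GeneratorConfig, generate_trial_set


class TestPercentChange:
    @pytest.mark.parametrize(
        "baseline,treated,expected",
        [
            (0.2072, 0.3012, 45),
            (0.2275, 0.2864, 26),
            (0.1937, 0.3012, 55),
            (0.1790, 0.2423, 35),
            (0.2439, 0.2850, 17),
            (0.2548, 0.2194, -14),
            (0.2072, 0.1937, -7),
        ],
    )
    def test_published_weighted_lag_pairs(self, baseline, treated, expected):
        assert percent_change(baseline, treated) == expected

    def test_zero_at_equality_and_sign(self):
        assert percent_change(0.25, 0.25) == 0
        assert percent_change(1.0, 1.2) > 0
        assert percent_change(1.2, 1.0) < 0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


def frechet_oracle(p, q):
    """Enumerate every monotone coupling of the two point sequences and
    minimize the maximum coupled distance."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)

    def dist(i, j):
        return np.linalg.norm(p[i] - q[j])

    n, m = len(p), len(q)
    best = [np.inf]

    def walk(i, j, cur):
        cur = max(cur, dist(i, j))
        if cur >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cur
            return
        if i + 1 < n:
            walk(i + 1, j, cur)
        if j + 1 < m:
            walk(i, j + 1, cur)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cur)

    walk(0, 0, 0.0)
    return best[0]


class TestDiscreteFrechet:
    def test_identical_trajectories(self, rng):
        p = rng.normal(size=(20, 3))
        assert discrete_frechet(p, p) == 0.0

    def test_constant_offset_segments(self):
        p = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        q = p + np.array([0.0, 0.5])
        assert discrete_frechet(p, q) == pytest.approx(0.5)

    def test_textbook_pair_matches_oracle(self):
        p = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        q = np.array([[0.0, 1.0], [2.0, 1.0]])
        assert discrete_frechet(p, q) == pytest.approx(frechet_oracle(p, q))

    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_pairs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(size=(rng.integers(2, 9), 2))
        q = rng.normal(size=(rng.integers(2, 9), 2))
        assert discrete_frechet(p, q) == pytest.approx(frechet_oracle(p, q))

    def test_symmetry_and_endpoint_bound(self, rng):
        p = rng.normal(size=(15, 3))
        q = rng.normal(size=(12, 3))
        d = discrete_frechet(p, q)
        assert d == pytest.approx(discrete_frechet(q, p))
        lower = max(np.linalg.norm(p[0] - q[0]), np.linalg.norm(p[-1] - q[-1]))
        assert d >= lower - 1e-12

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            discrete_frechet(np.zeros((3, 2)), np.zeros((3, 3)))


class TestFrechetBlock:
    @pytest.fixture
    def trajectories(self, rng):
        return [rng.normal(size=(30, 3)) for _ in range(4)]

    def test_self_block_diagonal_zero(self, trajectories):
        block = frechet_block(trajectories, trajectories, downsample=None)
        assert np.allclose(np.diag(block.per_pair), 0.0)
        assert np.allclose(block.per_pair, block.per_pair.T)

    def test_shared_dynamics_closer_than_distinct(self):
        base = dict(n_trials=4, duration=1.0, rate=500.0, noise_sd=0.02,
                    phase_jitter="none", freq_jitter_sd=0.0, envelope="constant")
        mk = lambda h, s: generate_trial_set(
            GeneratorConfig(harmonics=h, seed=s, **base))
        same_h = ((3.0, 1.0, 0.0), (5.0, 0.4, 0.9))
        other_h = ((2.0, 1.0, 0.0), (7.0, 0.8, 0.3))
        def embed_all(ts):
            from lfpattr.embed import embed_delay
            return [embed_delay(t, 3, 25) for t in ts]
        a1, a2 = embed_all(mk(same_h, 1)), embed_all(mk(same_h, 2))
        b = embed_all(mk(other_h, 3))
        same_block = frechet_block(a1, a2, downsample=100)
        diff_block = frechet_block(a1, b, downsample=100)
        assert same_block.block_mean < diff_block.block_mean
        # same dynamics: small relative to the ~1-unit amplitude scale
        assert same_block.block_mean < 0.5


class TestKSMatrix:
    def test_sample_vs_itself(self, rng):
        x = rng.normal(size=50)
        km = ks_matrix([x, x.copy()])
        assert km.max_D[0, 1] == 0.0
        assert km.same_class[0, 1]

    def test_disjoint_supports(self):
        km = ks_matrix([np.array([1.0, 2, 3, 4, 5]), np.array([10.0, 11, 12, 13, 14])])
        assert km.max_D[0, 1] == pytest.approx(1.0)
        assert not km.same_class[0, 1]

    def test_structure(self, rng):
        sets = [rng.normal(size=30) for _ in range(3)]
        km = ks_matrix(sets)
        assert np.allclose(km.max_D, km.max_D.T)
        assert np.all(np.diag(km.same_class))
        assert np.all((km.max_D >= 0) & (km.max_D <= 1))
        assert np.all(km.ln_p <= 0)

    def test_small_sample_flagged(self, rng):
        km = ks_matrix([rng.normal(size=3), rng.normal(size=30)])
        assert not km.valid[0, 1]
        assert np.isnan(km.max_D[0, 1])

    def test_type_i_error_calibration(self):
        # two same-distribution lag samples per replicate; the rejection
        # rate at alpha=0.05 must sit inside a wide binomial band
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.lognormal(mean=-1.5, sigma=0.3, size=100)
            b = rng.lognormal(mean=-1.5, sigma=0.3, size=100)
            km = ks_matrix([a, b])
            rejections += not km.same_class[0, 1]
        rate = rejections / n_rep
        # 0.05 +/- 3 binomial standard errors
        assert 0.004 <= rate <= 0.096


def test_generator_lag_shift_detected_by_ks():
    # scaling the target correlation time by 1.5x must separate the
    # per-trial lag distributions at the 5% level
    base = dict(n_trials=100, duration=1.0, rate=1000.0, noise_sd=0.05,
                freq_jitter_sd=0.3)
    cfg_a = GeneratorConfig(target_correlation_time=0.10, seed=21, **base)
    cfg_b = GeneratorConfig(target_correlation_time=0.15, seed=22, **base)
    lags = []
    for cfg in (cfg_a, cfg_b):
        ts = generate_trial_set(cfg)
        lags.append(np.array([autocorr_lag(t).lag_seconds for t in ts]))
    km = ks_matrix(lags)
    assert not km.same_class[0, 1]
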