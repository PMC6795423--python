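"""Cross-condition statistics: lag percent changes, KS matrices, Fréchet blocks.

Three complementary views of how a pharmacological condition moves the
dynamics: the signed integer percent change of the weighted-average lag
time (the scalar headline statistic), two-sample Kolmogorov-Smirnov
comparison of whole lag-time distributions, and the discrete Fréchet
distance between reconstructed attractors (pure trajectory geometry,
blind to traversal speed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import ks_2samp

from .embed import EmbeddedTrajectory, LagDistribution

__all__ = [
    "percent_change",
    "KSMatrix",
    "ks_matrix",
    "discrete_frechet",
    "FrechetBlock",
    "frechet_block",
]

LN_P_FLOOR = -745.0  # exp underflow guard for log p-values

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False


def percent_change(baseline: float, treated: float) -> int:
    """Integer percent change of ``treated`` relative to ``baseline``.

    100*(treated - baseline)/baseline, rounded half away from zero to the
    nearest integer -- the rounding that reproduces published integer
    percents (e.g. a 6.515% shortening prints as 7%).
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    x = 100.0 * (treated - baseline) / baseline
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class KSMatrix:
    """Pairwise two-sample KS results over per-trial lag samples.

    ``same_class[i, j]`` is True when the test fails to reject equality of
    distributions i and j at level alpha; ``ln_p`` is the natural-log
    p-value (floored at the exp underflow limit) and ``max_D`` the
    supremum ECDF difference.  Entries for samples below the minimum size
    are NaN with ``valid`` False.
    """

    labels: list[str]
    same_class: np.ndarray
    ln_p: np.ndarray
    max_D: np.ndarray
    alpha: float
    valid: np.ndarray


def _lag_values(d) -> np.ndarray:
    if isinstance(d, LagDistribution):
        return d.lag_seconds
    return np.asarray(d, dtype=float)


def ks_matrix(
    distributions: Sequence,
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
    min_n: int = 5,
) -> KSMatrix:
    """All-pairs two-sample KS test on raw per-trial lag values (not binned).

    Uses the exact ECDF sup-difference with the asymptotic p-value
    (adequate at the ~100 trials per condition this targets; approximate
    for much smaller samples).
    """
    samples = [_lag_values(d) for d in distributions]
    m = len(samples)
    if labels is None:
        labels = [f"set{i}" for i in range(m)]
    labels = list(labels)
    ok = np.array([s.size >= min_n for s in samples])
    same = np.zeros((m, m), dtype=bool)
    ln_p = np.full((m, m), np.nan)
    max_d = np.full((m, m), np.nan)
    valid = np.zeros((m, m), dtype=bool)
    for i in range(m):
        if not ok[i]:
            continue
        same[i, i] = True
        ln_p[i, i] = 0.0
        max_d[i, i] = 0.0
        valid[i, i] = True
        for j in range(i + 1, m):
            if not ok[j]:
                continue
            res = ks_2samp(samples[i], samples[j], method="asymp")
            d = float(res.statistic)
            lp = float(np.log(res.pvalue)) if res.pvalue > 0 else LN_P_FLOOR
            lp = max(lp, LN_P_FLOOR)
            same[i, j] = same[j, i] = res.pvalue >= alpha
            ln_p[i, j] = ln_p[j, i] = lp
            max_d[i, j] = max_d[j, i] = d
            valid[i, j] = valid[j, i] = True
    return KSMatrix(labels=labels, same_class=same, ln_p=ln_p,
                    max_D=max_d, alpha=alpha, valid=valid)


# ---------------------------------------------------------------------------
# Discrete Fréchet distance


def _frechet_dp_py(dmat: np.ndarray) -> float:
    n, m = dmat.shape
    prev = np.empty(m)
    prev[0] = dmat[0, 0]
    for j in range(1, m):
        prev[j] = max(prev[j - 1], dmat[0, j])
    cur = np.empty(m)
    for i in range(1, n):
        cur[0] = max(prev[0], dmat[i, 0])
        for j in range(1, m):
            cur[j] = max(min(prev[j], prev[j - 1], cur[j - 1]), dmat[i, j])
        prev, cur = cur, prev
    return float(prev[m - 1])


if _HAVE_NUMBA:

    @njit(cache=False)
    def _frechet_dp(dmat):  # pragma: no cover - exercised via discrete_frechet
        n, m = dmat.shape
        prev = np.empty(m)
        prev[0] = dmat[0, 0]
        for j in range(1, m):
            prev[j] = max(prev[j - 1], dmat[0, j])
        cur = np.empty(m)
        for i in range(1, n):
            cur[0] = max(prev[0], dmat[i, 0])
            for j in range(1, m):
                best = prev[j]
                if prev[j - 1] < best:
                    best = prev[j - 1]
                if cur[j - 1] < best:
                    best = cur[j - 1]
                cur[j] = best if best > dmat[i, j] else dmat[i, j]
            for j in range(m):
                prev[j] = cur[j]
        return prev[m - 1]

else:  # pragma: no cover
    _frechet_dp = _frechet_dp_py


def _points(traj) -> np.ndarray:
    if isinstance(traj, EmbeddedTrajectory):
        pts = traj.points
    else:
        pts = np.asarray(traj, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    return pts


def discrete_frechet(p, q) -> float:
    """Coupling-minimax (discrete Fréchet) distance between two polylines.

    The man-walking-a-dog distance: the shortest leash that lets both
    walkers traverse their curves monotonically.  Standard O(nm) dynamic
    program over the pairwise-distance grid; symmetric, zero iff the
    point sequences coincide, and bounded below by the endpoint
    distances (endpoints are always coupled).
    """
    pp = _points(p)
    qq = _points(q)
    if pp.size == 0 or qq.size == 0:
        raise ValueError("trajectories must be nonempty")
    if pp.shape[1] != qq.shape[1]:
        raise ValueError("trajectories must share dimension")
    dmat = np.sqrt(((pp[:, None, :] - qq[None, :, :]) ** 2).sum(axis=2))
    return float(_frechet_dp(dmat))


def _downsample(pts: np.ndarray, target: int) -> np.ndarray:
    if target is None or pts.shape[0] <= target:
        return pts
    idx = np.linspace(0, pts.shape[0] - 1, target).round().astype(int)
    return pts[idx]


@dataclass
class FrechetBlock:
    """All-pairs Fréchet distances between two trajectory ensembles."""

    per_pair: np.ndarray
    block_mean: float
    block_sd: float
    downsample: int | None


def frechet_block(
    set_a: Sequence, set_b: Sequence, downsample: int | None = 400,
    normalize: bool = False,
) -> FrechetBlock:
    """Pairwise Fréchet distances between every trajectory of two sets.

    Trajectories are uniformly downsampled before the dynamic program
    (the distance is a topology-level comparison; the full 10^4-point
    grids would cost O(nm) each for no interpretive gain).  With
    ``normalize`` each trajectory is scaled to unit RMS radius first;
    the default compares raw amplitudes.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("both trajectory sets must be nonempty")
    pts_a = [_downsample(_points(t), downsample) for t in set_a]
    pts_b = [_downsample(_points(t), downsample) for t in set_b]
    if normalize:
        def _norm(p):
            c = p - p.mean(axis=0)
            r = np.sqrt((c ** 2).sum(axis=1).mean())
            return c / r if r > 0 else c
        pts_a = [_norm(p) for p in pts_a]
        pts_b = [_norm(p) for p in pts_b]
    out = np.empty((len(pts_a), len(pts_b)))
    for i, pa in enumerate(pts_a):
        for j, pb in enumerate(pts_b):
            out[i, j] = discrete_frechet(pa, pb)
    return FrechetBlock(
        per_pair=out,
        block_mean=float(out.mean()),
        block_sd=float(out.std()),
        downsample=downsample,
    )
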