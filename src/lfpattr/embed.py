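"""Delay-embedding reconstruction: lag selection, FNN dimension, trajectories.

A scalar series ``x_i = x(i dt)`` is expanded into delay vectors
``(x_i, x_{i+n}, ..., x_{i+(d-1)n})`` with lag ``tau = n dt``.  The lag is
chosen either at the first zero crossing of the autocorrelation (full
linear decorrelation) or at the first minimum of the average mutual
information (AMI), and the embedding dimension by the false-nearest-
neighbor (FNN) criterion: raise ``d`` until lifting to ``d+1`` no longer
blows up nearest-neighbor distances by more than a ratio ``f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .dataio import Trial, TrialSet

__all__ = [
    "LagEstimate",
    "LagDistribution",
    "FNNCurve",
    "EmbeddedTrajectory",
    "autocorr_lag",
    "ami_lag",
    "average_mutual_information",
    "fnn_curve",
    "max_feasible_dim",
    "min_embedding_dim",
    "embed_delay",
    "lag_distribution",
    "NoCrossingError",
    "NoMinimumError",
]


class NoCrossingError(ValueError):
    """The autocorrelation never reaches zero within the search horizon."""


class NoMinimumError(ValueError):
    """The AMI has no strict local minimum within the search horizon."""


@dataclass(frozen=True)
class LagEstimate:
    """A lag in integer samples; ``lag_seconds = n / rate`` exactly."""

    lag_samples: int
    rate: float
    method: str  # {"autocorr_zero", "ami_min"}

    def __post_init__(self) -> None:
        if self.lag_samples < 1:
            raise ValueError("lag must be at least one sample")

    @property
    def lag_seconds(self) -> float:
        return self.lag_samples / self.rate


def _series(obj) -> tuple[np.ndarray, float]:
    if isinstance(obj, Trial):
        return obj.samples, obj.rate
    x = np.asarray(obj, dtype=float)
    return x, 1.0


def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (divide-by-N), mean-removed autocorrelation, lags 0..max_lag."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f))[: max_lag + 1] / n
    if acov[0] <= 0:
        raise ValueError("autocorrelation undefined for a constant series")
    return acov / acov[0]


def autocorr_lag(trial, max_lag: int | None = None) -> LagEstimate:
    """Lag at the first zero crossing of the autocorrelation.

    Returns the smallest positive lag whose normalized autocorrelation is
    <= 0 (a tiny absolute tolerance absorbs floating-point zeros such as
    the exact quarter-period zero of a sampled sinusoid).
    """
    x, rate = _series(trial)
    if max_lag is None:
        max_lag = x.size // 2
    rho = autocorrelation(x, max_lag)
    idx = np.nonzero(rho[1:] <= 1e-10)[0]
    if idx.size == 0:
        raise NoCrossingError(
            f"no autocorrelation zero crossing within {max_lag} samples"
        )
    return LagEstimate(int(idx[0]) + 1, rate, "autocorr_zero")


def _equiprobable_codes(x: np.ndarray, bins: int) -> np.ndarray:
    """Rank-based assignment of samples to ``bins`` equal-count bins."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(x.size)
    return (ranks * bins) // x.size


def average_mutual_information(
    x: np.ndarray, lag: int, bins: int = 16, codes: np.ndarray | None = None
) -> float:
    """Plug-in mutual information (nats) of (x_t, x_{t+lag}), equiprobable bins.

    Rank-based binning makes the estimate invariant under strictly
    monotone transforms of the samples.
    """
    x = np.asarray(x, dtype=float)
    if codes is None:
        codes = _equiprobable_codes(x, bins)
    a = codes[:-lag]
    b = codes[lag:]
    m = a.size
    joint = np.bincount(a * bins + b, minlength=bins * bins).astype(float)
    joint /= m
    pa = joint.reshape(bins, bins).sum(axis=1)
    pb = joint.reshape(bins, bins).sum(axis=0)
    nz = joint > 0
    outer = np.outer(pa, pb).ravel()
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def ami_lag(trial, bins: int = 16, max_lag: int | None = None) -> LagEstimate:
    """Lag at the first (prominent) local minimum of the AMI.

    The plug-in MI estimate fluctuates at the scale of its chi-square
    bias, ``(bins-1)^2 / 2m``, so a literal strict-local-minimum rule
    fires on estimator wiggles at tiny lags.  A candidate minimum here
    counts only once the AMI has risen above it by that bias scale; the
    returned lag is the running minimum at the moment of confirmation.
    A monotone (never-confirming) AMI raises :class:`NoMinimumError`.
    """
    x, rate = _series(trial)
    if bins < 2:
        raise ValueError("need at least two bins")
    if np.ptp(x) == 0:
        raise ValueError("AMI undefined for a constant series")
    if max_lag is None:
        max_lag = x.size // 2
    codes = _equiprobable_codes(x, bins)
    tol = (bins - 1) ** 2 / (2.0 * max(x.size - 1, 1))
    best = average_mutual_information(x, 1, bins, codes)
    best_lag = 1
    for lag in range(2, max_lag + 1):
        cur = average_mutual_information(x, lag, bins, codes)
        if cur < best:
            best, best_lag = cur, lag
        elif cur > best + tol:
            return LagEstimate(best_lag, rate, "ami_min")
    raise NoMinimumError(f"no AMI local minimum within {max_lag} samples")


@dataclass
class EmbeddedTrajectory:
    """Delay-coordinate path: points[i] = (x_i, x_{i+n}, ..., x_{i+(d-1)n})."""

    points: np.ndarray
    d: int
    n: int

    def __len__(self) -> int:
        return self.points.shape[0]


def embed_delay(trial, d: int, lag: LagEstimate | int) -> EmbeddedTrajectory:
    """Embed a series in ``d`` dimensions with lag ``n`` samples.

    Point count is ``N - (d-1) n``; every coordinate is a view-exact copy
    of the source series at the prescribed offset.
    """
    x, _ = _series(trial)
    n = lag.lag_samples if isinstance(lag, LagEstimate) else int(lag)
    if d < 1 or n < 1:
        raise ValueError("dimension and lag must be positive")
    m = x.size - (d - 1) * n
    if m <= 0:
        raise ValueError(
            f"series of length {x.size} too short for d={d}, lag={n}"
        )
    pts = np.column_stack([x[j * n : j * n + m] for j in range(d)])
    return EmbeddedTrajectory(pts, d=d, n=n)


@dataclass
class FNNCurve:
    """Percentage of false nearest neighbors per embedding dimension."""

    dims: np.ndarray
    fnn_percent: np.ndarray
    f: float
    theiler: int
    tau: int
    n_points: np.ndarray = field(default=None)


def _nearest_excluding(
    pts: np.ndarray, theiler: int
) -> tuple[np.ndarray, np.ndarray]:
    """Index and distance of each point's nearest neighbor with |i-j| > theiler."""
    m = pts.shape[0]
    tree = cKDTree(pts)
    # temporally adjacent points are also spatially adjacent on a smooth
    # trajectory, so the Theiler-excluded window must be searched past
    k = min(m, 2 * theiler + 8)
    nn_idx = np.full(m, -1, dtype=np.int64)
    nn_dist = np.full(m, np.inf)
    pending = np.arange(m)
    while pending.size:
        dist, idx = tree.query(pts[pending], k=k)
        if k == 1:
            dist = dist[:, None]
            idx = idx[:, None]
        valid = np.abs(idx - pending[:, None]) > theiler
        has = valid.any(axis=1)
        first = np.argmax(valid, axis=1)
        rows = np.nonzero(has)[0]
        nn_idx[pending[rows]] = idx[rows, first[rows]]
        nn_dist[pending[rows]] = dist[rows, first[rows]]
        pending = pending[~has]
        if k >= m:
            break
        k = min(m, k * 4)
    return nn_idx, nn_dist


def max_feasible_dim(n_samples: int, lag: LagEstimate | int, theiler: int) -> int:
    """Largest dimension the FNN lift can evaluate on a series.

    Dimension d needs ``n_samples - d*lag`` points for the (d+1)-lift,
    with enough of them outside the Theiler exclusion zone.
    """
    n = lag.lag_samples if isinstance(lag, LagEstimate) else int(lag)
    d = (n_samples - theiler - 3) // n
    if d < 1:
        raise ValueError("series too short for any embedding at this lag")
    return d


def fnn_curve(
    trial,
    lag: LagEstimate | int,
    f: float = 12.0,
    theiler: int = 500,
    d_max: int = 6,
) -> FNNCurve:
    """False-nearest-neighbor percentages for dimensions 1..d_max.

    For each ``d``, embed, find every point's nearest neighbor outside the
    Theiler window, and call the pair *false* when the extra coordinate of
    the (d+1)-lift grows their distance by more than the ratio ``f``
    (Kennel's distance-ratio criterion).
    """
    x, _ = _series(trial)
    n = lag.lag_samples if isinstance(lag, LagEstimate) else int(lag)
    if f <= 0:
        raise ValueError("distance ratio f must be positive")
    dims = np.arange(1, d_max + 1)
    pct = np.empty(d_max)
    counts = np.empty(d_max, dtype=int)
    for d in dims:
        # keep only points that can be lifted to d+1 dimensions
        m = x.size - d * n
        if m <= theiler + 2:
            raise ValueError(
                f"series too short for d={d} with lag {n} and Theiler {theiler}"
            )
        pts = np.column_stack([x[j * n : j * n + m] for j in range(d)])
        nn_idx, nn_dist = _nearest_excluding(pts, theiler)
        lifted = x[d * n : d * n + m]
        lift_gap = np.abs(lifted - lifted[nn_idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = lift_gap / nn_dist
        # exact revisits of a periodic orbit land at rounding-level
        # distances; a gap at numerical precision cannot indicate a
        # failure to unfold
        num_floor = 1e-9 * np.ptp(x)
        ratio[lift_gap <= num_floor] = 0.0
        ok = nn_idx >= 0
        pct[d - 1] = 100.0 * np.mean(ratio[ok] > f)
        counts[d - 1] = int(ok.sum())
    return FNNCurve(dims=dims, fnn_percent=pct, f=f, theiler=theiler,
                    tau=n, n_points=counts)


def min_embedding_dim(curve: FNNCurve, threshold: float = 0.1) -> int:
    """Smallest dimension whose FNN percentage falls below ``threshold``."""
    below = np.nonzero(curve.fnn_percent < threshold)[0]
    if below.size == 0:
        raise ValueError(
            f"FNN never dropped below {threshold}% up to d={curve.dims[-1]}"
        )
    return int(curve.dims[below[0]])


@dataclass
class LagDistribution:
    """Per-trial lag estimates with histogram and weighted-average summary."""

    per_trial: list[LagEstimate]
    lag_seconds: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    weighted_mean: float
    method: str
    excluded_faulty: list[int]
    excluded_no_estimate: list[int]


def lag_distribution(
    tset: TrialSet,
    method: str = "autocorr",
    bin_width: float = 0.05,
    bin_max: float = 0.7,
    faulty_peak_to_peak: float = 0.04,
    bins_ami: int = 16,
) -> LagDistribution:
    """Per-trial lag estimates for a trial set, with faulty-trial screening.

    Trials whose peak-to-peak amplitude falls below the faulty-coupling
    threshold are excluded and reported, as are trials where the estimator
    finds no crossing/minimum.  The weighted mean is the count-weighted
    mean over the empirical lag distribution (i.e. the mean of the
    per-trial lags), the scalar summary used for condition comparisons.
    """
    if method not in ("autocorr", "ami"):
        raise ValueError(f"unknown lag method {method!r}")
    estimates: list[LagEstimate] = []
    excluded_faulty: list[int] = []
    excluded_no_estimate: list[int] = []
    for t in tset:
        if t.peak_to_peak < faulty_peak_to_peak:
            excluded_faulty.append(t.trial_index)
            continue
        try:
            if method == "autocorr":
                est = autocorr_lag(t)
            else:
                est = ami_lag(t, bins=bins_ami)
        except (NoCrossingError, NoMinimumError):
            excluded_no_estimate.append(t.trial_index)
            continue
        estimates.append(est)
    if not estimates:
        raise ValueError("no trial yielded a valid lag estimate")
    lags = np.array([e.lag_seconds for e in estimates])
    upper = max(bin_max, float(lags.max()) + bin_width)
    edges = np.arange(0.0, upper + bin_width, bin_width)
    counts, _ = np.histogram(lags, bins=edges)
    return LagDistribution(
        per_trial=estimates,
        lag_seconds=lags,
        bin_edges=edges,
        counts=counts,
        weighted_mean=float(lags.mean()),
        method=method,
        excluded_faulty=excluded_faulty,
        excluded_no_estimate=excluded_no_estimate,
    )
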