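"""Top-k Fourier modeling of trials and residual diagnostics.

Each trial is decomposed by the DFT and re-synthesized from only the k
harmonics of largest amplitude,

    x(t) ~ a0 + 2 * sum_k A_k cos(2 pi f0 k t + theta_k),

with f0 = 1/T the fundamental of the analyzed window.  The residual
(original minus synthesis) is then screened with augmented Dickey-Fuller
and KPSS stationarity tests and a Ljung-Box whiteness test: when a small
k already leaves a stationary, serially uncorrelated residual, those k
harmonics carry the entire trend of the sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tools.sm_exceptions import InterpolationWarning
from statsmodels.tsa.stattools import adfuller, kpss

from .dataio import Trial, TrialSet

__all__ = [
    "FourierModel",
    "ResidualDiagnostics",
    "top_k_synthesize",
    "residual_tests",
    "synthesis_adequacy",
    "amplitude_summary",
    "frequency_of_index",
]


@dataclass
class FourierModel:
    """Top-k harmonic representation of one trial.

    ``k_indices`` are integer DFT frequency indices (largest amplitudes
    first), ``amplitudes``/``phases`` their polar Fourier coefficients
    A_k, theta_k; ``synthesized + residual == original`` exactly by
    construction.
    """

    k_indices: np.ndarray
    amplitudes: np.ndarray
    phases: np.ndarray
    dc: float
    fundamental: float
    synthesized: np.ndarray
    residual: np.ndarray
    rate: float

    @property
    def k(self) -> int:
        return self.k_indices.size


def top_k_synthesize(trial, k: int) -> FourierModel:
    """Retain the DC term plus the k strongest positive-frequency harmonics.

    "Strongest" means largest |a_k|; ties break toward the lower index.
    Synthesis inverts the masked spectrum, so retaining every harmonic
    reproduces the trial to machine precision.
    """
    if isinstance(trial, Trial):
        x, rate = trial.samples, trial.rate
    else:
        x, rate = np.asarray(trial, dtype=float), 1.0
    n = x.size
    n_pos = n // 2  # positive-frequency indices 1..n//2 (incl. Nyquist if even)
    if not 1 <= k <= n_pos:
        raise ValueError(f"k={k} outside 1..{n_pos}")
    spec = np.fft.rfft(x)
    mags = np.abs(spec[1:]) / n
    # stable sort on descending magnitude -> lower index wins ties
    order = np.argsort(-mags, kind="stable") + 1
    selected = np.sort(order[:k])
    mask = np.zeros(spec.size, dtype=bool)
    mask[0] = True
    mask[selected] = True
    synthesized = np.fft.irfft(np.where(mask, spec, 0.0), n)
    residual = x - synthesized
    # report in the order of decreasing amplitude
    sel_sorted = order[:k]
    return FourierModel(
        k_indices=sel_sorted,
        amplitudes=np.abs(spec[sel_sorted]) / n,
        phases=np.angle(spec[sel_sorted]),
        dc=float(spec[0].real) / n,
        fundamental=rate / n,
        synthesized=synthesized,
        residual=residual,
        rate=rate,
    )


@dataclass
class ResidualDiagnostics:
    """Stationarity and whiteness verdicts for a synthesis residual at alpha."""

    adf_stationary: bool
    kpss_stationary: bool
    white_noise: bool
    residual_sd: float
    adf_p: float
    kpss_p: float
    ljungbox_p: float


def residual_tests(
    residual: np.ndarray, alpha: float = 0.05, lb_lags: int = 20
) -> ResidualDiagnostics:
    """ADF + KPSS stationarity and Ljung-Box whiteness screening.

    ADF rejects a unit root (p < alpha => stationary); KPSS fails to
    reject level-stationarity (p >= alpha => stationary; the level null
    because residuals are mean-zero by construction); whiteness is a
    portmanteau autocorrelation test at ``lb_lags`` lags, an equivalent
    null to an ARMA(0,0) identification.
    """
    r = np.asarray(residual, dtype=float)
    if r.size < 50:
        raise ValueError("residual too short for stationarity testing")
    if np.ptp(r) == 0:
        raise ValueError("constant residual: diagnostics undefined")
    adf_p = float(adfuller(r, regression="c", autolag="AIC")[1])
    with warnings.catch_warnings():
        # the KPSS statistic routinely falls outside the tabulated p range
        warnings.simplefilter("ignore", InterpolationWarning)
        kpss_p = float(kpss(r, regression="c", nlags="auto")[1])
    lb = acorr_ljungbox(r, lags=[lb_lags])
    lb_p = float(lb["lb_pvalue"].iloc[0])
    return ResidualDiagnostics(
        adf_stationary=adf_p < alpha,
        kpss_stationary=kpss_p >= alpha,
        white_noise=lb_p >= alpha,
        residual_sd=float(r.std()),
        adf_p=adf_p,
        kpss_p=kpss_p,
        ljungbox_p=lb_p,
    )


def synthesis_adequacy(
    trial, ks: Sequence[int] = (3, 5, 10), alpha: float = 0.05
) -> int | None:
    """Smallest tested k whose residual passes both stationarity tests.

    Returns None when no tested budget is adequate (the residual still
    carries trend for every k in ``ks``).
    """
    ks = list(ks)
    if ks != sorted(ks):
        raise ValueError("ks must be sorted ascending")
    for k in ks:
        model = top_k_synthesize(trial, k)
        diag = residual_tests(model.residual, alpha=alpha)
        if diag.adf_stationary and diag.kpss_stationary:
            return k
    return None


def amplitude_summary(tset: TrialSet, k: int) -> pd.DataFrame:
    """Which frequency indices the per-trial top-k sets use, and how strongly.

    One row per frequency index ever selected: the percentage of trials
    whose top-k set contains it and the mean +/- sd amplitude over those
    trials.  The percentages sum to k x 100 because each trial
    contributes exactly k selections.
    """
    models = [top_k_synthesize(t, k) for t in tset]
    by_index: dict[int, list[float]] = {}
    for m in models:
        for ki, amp in zip(m.k_indices, m.amplitudes):
            by_index.setdefault(int(ki), []).append(float(amp))
    fundamental = models[0].fundamental
    rows = []
    for ki in sorted(by_index):
        amps = np.array(by_index[ki])
        rows.append(
            {
                "k_index": ki,
                "frequency_hz": frequency_of_index(ki, fundamental),
                "percent_of_trials": 100.0 * amps.size / len(tset),
                "amplitude_mean": float(amps.mean()),
                "amplitude_sd": float(amps.std()),
            }
        )
    return pd.DataFrame(rows)


def frequency_of_index(k_index: int, fundamental: float = 1.0 / 3.0) -> float:
    """Physical frequency of DFT index k: ``k * fundamental`` Hz.

    The shipped default fundamental is 1/3 Hz for display parity with the
    published coefficient tables; pass ``rate / n_samples`` (= 1/T of the
    analyzed window) for exact correspondence with a FourierModel.
    """
    if k_index < 0:
        raise ValueError("frequency index must be non-negative")
    return k_index * fundamental
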