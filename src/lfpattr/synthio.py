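"""Synthetic LFP trial generator.

The recordings this package analyses are not deposited anywhere, so every
stage is exercised on surrogate trial sets that reproduce the statistical
structure the analysis assumes:

* quasi-periodic oscillations built from a small number of low-frequency
  harmonics (a handful of Fourier coefficients captures the trend of the
  real sweeps, so a harmonic-sum generative model keeps the generator and
  the spectral module mutually consistent);
* a random stimulus phase per trial (the light pulse hits the ongoing
  rhythm at a random phase, which is what circular alignment corrects);
* trial-to-trial spread of the correlation time (per-trial frequency
  jitter), giving the broad lag-time distributions the study reports;
* an optional slow amplitude decay of the evoked response;
* occasional "faulty coupling" trials: pure noise with a peak-to-peak
  amplitude below 0.04 units.

One root seed is fanned out into independent per-trial child streams, so
output is bit-reproducible and individual trials can be regenerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .dataio import ConditionLabel, Trial, TrialSet

__all__ = [
    "GeneratorConfig",
    "generate_trial_set",
    "make_two_condition_set",
    "analytic_first_zero",
    "DEFAULT_HARMONICS",
]

# Two non-harmonically-related components in the 2-8 Hz band (7:3 ratio).
# The secondary amplitude is tuned so the autocorrelation first zero
# crossing tau* satisfies f2 * tau* ~ 1/2: at that delay the fourth delay
# coordinate is (nearly) a linear combination of the first three, so the
# delay trajectory folds in two dimensions but embeds cleanly and with a
# bounded neighbor-distance growth factor in three -- the regime the
# study's sweeps live in (d_E = 3).  Calibrated over seeds; see
# docs/methods.md for the geometry.
DEFAULT_HARMONICS: tuple[tuple[float, float, float], ...] = (
    (2.0, 1.0, 0.0),
    (14.0 / 3.0, 0.472, 2.7),
)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic trial generator.

    ``harmonics`` is a list of ``(frequency_hz, amplitude, phase_rad)``
    triples.  ``target_correlation_time`` rescales all harmonic
    frequencies so that the analytic first zero crossing of the signal's
    autocorrelation lands on the requested lag (seconds), giving a
    closed-form oracle for lag recovery.  ``freq_jitter_sd`` is the
    log-scale standard deviation of a per-trial multiplicative frequency
    jitter; it produces the trial-to-trial spread of correlation times
    seen in the recordings and is centred so the *mean* lag stays on
    target.  Faulty-coupling trials are white noise rescaled below
    ``faulty_peak_to_peak_max``.
    """

    n_trials: int = 100
    duration: float = 2.0
    rate: float = 10_000.0
    harmonics: Sequence[tuple[float, float, float]] = DEFAULT_HARMONICS
    envelope: str = "linear_decay"     # {"constant", "linear_decay"}
    envelope_floor: float = 0.3        # terminal fraction of the initial amplitude
    # 5% of the default waveform's RMS amplitude (~0.53 signal units)
    noise_sd: float = 0.026
    noise_band: float | None = 130.0   # Hz; low-pass corner of the additive noise
    noise_spectrum: str = "white"      # {"white", "pink"}; shape inside the band
    noise_corner: float = 2.0          # Hz; 1/f rolloff start for pink noise
    phase_jitter: str = "uniform_circular"   # {"uniform_circular", "none"}
    freq_jitter_sd: float = 0.3
    target_correlation_time: float | None = None
    faulty_fraction: float = 0.0
    faulty_peak_to_peak_max: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        n = self.duration * self.rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration x rate = {n} is not an integer sample count"
            )
        if not 0.0 <= self.faulty_fraction <= 1.0:
            raise ValueError("faulty_fraction must lie in [0, 1]")
        if self.envelope not in ("constant", "linear_decay"):
            raise ValueError(f"unknown envelope {self.envelope!r}")
        if self.phase_jitter not in ("uniform_circular", "none"):
            raise ValueError(f"unknown phase_jitter {self.phase_jitter!r}")
        if self.noise_spectrum not in ("white", "pink"):
            raise ValueError(f"unknown noise_spectrum {self.noise_spectrum!r}")
        if not self.harmonics:
            raise ValueError("at least one harmonic is required")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.rate))

    def scaled_harmonics(self) -> list[tuple[float, float, float]]:
        """Harmonics after the optional correlation-time rescaling."""
        harmonics = [tuple(h) for h in self.harmonics]
        if self.target_correlation_time is not None:
            t0 = analytic_first_zero(harmonics)
            s = t0 / self.target_correlation_time
            harmonics = [(f * s, a, p) for f, a, p in harmonics]
        return harmonics


def analytic_first_zero(
    harmonics: Sequence[tuple[float, float, float]], t_max: float = 10.0
) -> float:
    """First zero crossing of the autocorrelation of a harmonic sum.

    For x(t) = sum_k A_k cos(2 pi f_k t + phi_k) with a uniformly random
    global phase, the autocorrelation is rho(tau) proportional to
    sum_k A_k^2 cos(2 pi f_k tau); its first zero is found by bracketing
    on a fine grid and polishing with Brent's method.
    """
    freqs = np.array([h[0] for h in harmonics])
    w = np.array([h[1] ** 2 for h in harmonics])

    def rho(tau):
        return float(np.sum(w * np.cos(2 * np.pi * freqs * tau)))

    f_max = freqs.max()
    grid = np.arange(0.0, t_max, 1.0 / (200.0 * f_max))
    vals = (w[None, :] * np.cos(2 * np.pi * grid[:, None] * freqs[None, :])).sum(axis=1)
    idx = np.nonzero(vals <= 0.0)[0]
    if idx.size == 0:
        raise ValueError("autocorrelation has no zero crossing on the grid")
    i = idx[0]
    if vals[i] == 0.0:
        return float(grid[i])
    return float(brentq(rho, grid[i - 1], grid[i]))


def _envelope(config: GeneratorConfig, t: np.ndarray) -> np.ndarray:
    if config.envelope == "constant":
        return np.ones_like(t)
    # linear decay from 1 at t=0 to envelope_floor at the end of the sweep
    return 1.0 + (config.envelope_floor - 1.0) * t / config.duration


def _noise(rng: np.random.Generator, n: int, config: GeneratorConfig) -> np.ndarray:
    """Additive Gaussian noise, band-limited like the acquisition chain.

    The recordings are band-passed online at 0.1-130 Hz before analysis,
    so the in-band noise is smooth at the 10 kHz sampling rate.  White
    Gaussian noise is low-passed at ``noise_band`` in the frequency domain
    and rescaled to the requested standard deviation; ``noise_band=None``
    yields plain white noise.
    """
    eps = rng.standard_normal(n)
    shaped = config.noise_spectrum == "pink"
    banded = config.noise_band is not None and config.noise_band < config.rate / 2
    if shaped or banded:
        spec = np.fft.rfft(eps)
        freqs = np.fft.rfftfreq(n, d=1.0 / config.rate)
        if shaped:
            # 1/f amplitude rolloff above the corner, flat below it
            spec *= 1.0 / np.maximum(freqs / config.noise_corner, 1.0)
        if banded:
            spec[freqs > config.noise_band] = 0.0
        spec[0] = 0.0
        eps = np.fft.irfft(spec, n)
        sd = eps.std()
        if sd > 0:
            eps /= sd
    return config.noise_sd * eps


def generate_trial_set(config: GeneratorConfig) -> TrialSet:
    """Generate one synthetic trial ensemble.

    Each regular trial is ``sum_k A_k env(t) cos(2 pi f_k t + phi_k +
    phi_trial)`` plus white Gaussian noise; ``phi_trial`` is drawn
    uniformly per trial when ``phase_jitter="uniform_circular"``.
    Deterministic given the seed.
    """
    n = config.n_samples
    t = np.arange(n) / config.rate
    env = _envelope(config, t)
    harmonics = config.scaled_harmonics()

    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_trials + 1)
    # the extra stream assigns faulty-trial slots, independent of trial content
    slot_rng = np.random.default_rng(children[-1])
    n_faulty = int(round(config.faulty_fraction * config.n_trials))
    faulty_idx = set(
        slot_rng.choice(config.n_trials, size=n_faulty, replace=False).tolist()
    )

    trials = []
    for i in range(config.n_trials):
        rng = np.random.default_rng(children[i])
        if i in faulty_idx:
            x = rng.standard_normal(n)
            x = x / np.ptp(x) * (0.6 * config.faulty_peak_to_peak_max)
        else:
            # the light pulse catches the ongoing rhythm at a random time,
            # so the oscillation is shifted by a random t0 (a circular time
            # shift: every component advances by 2 pi f t0) while the
            # evoked envelope stays stimulus-locked
            t0 = (
                rng.uniform(0.0, config.duration)
                if config.phase_jitter == "uniform_circular"
                else 0.0
            )
            if config.freq_jitter_sd > 0.0:
                # E[1/s] = 1, so the mean correlation time stays on target
                s = float(
                    rng.lognormal(
                        mean=0.5 * config.freq_jitter_sd**2,
                        sigma=config.freq_jitter_sd,
                    )
                )
            else:
                s = 1.0
            x = np.zeros(n)
            for f, a, p in harmonics:
                x += a * np.cos(2 * np.pi * f * s * (t + t0) + p)
            x *= env
            if config.noise_sd > 0.0:
                x = x + _noise(rng, n, config)
        trials.append(
            Trial(x, rate=config.rate, mouse_id=0,
                  condition=ConditionLabel(), trial_index=i + 1)
        )
    return TrialSet(trials, label=ConditionLabel(), mouse_id=0)


def make_two_condition_set(
    config_a: GeneratorConfig, config_b: GeneratorConfig
) -> tuple[TrialSet, TrialSet]:
    """Generate a labeled (baseline, other) pair of trial sets.

    Mirrors the concatenation of 100 baseline trials with 100 treatment
    trials used by the overlap and KS analyses.  Both configs must share
    sampling rate and duration; when they differ only in seed the two
    sets are statistically exchangeable.
    """
    if config_a.rate != config_b.rate or config_a.duration != config_b.duration:
        raise ValueError("the two conditions must share rate and duration")
    return generate_trial_set(config_a), generate_trial_set(config_b)
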