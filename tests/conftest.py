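import numpy as np
import pytest

from lfpattr.dataio import ConditionLabel, Trial, TrialSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trialset(matrix, rate=1000.0):
    """Wrap a (n_trials, n_samples) matrix as a TrialSet."""
    matrix = np.asarray(matrix, dtype=float)
    trials = [
        Trial(matrix[i], rate=rate, trial_index=i + 1) for i in range(matrix.shape[0])
    ]
    return TrialSet(trials, label=ConditionLabel(), mouse_id=0)


@pytest.fixture
def small_quasiperiodic_set():
    """Eight short quasi-periodic trials with random stimulus phase."""
    from lfpattr.synthio import GeneratorConfig, generate_trial_set

    cfg = GeneratorConfig(
        n_trials=8, duration=1.0, rate=1000.0,
        harmonics=((3.0, 1.0, 0.0), (5.0, 0.4, 0.9)),
        noise_sd=0.02, noise_band=130.0, freq_jitter_sd=0.0, seed=7,
    )
    return generate_trial_set(cfg)
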