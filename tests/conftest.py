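import numpy as np
import pytest

from courtload import synth, pipeline as pl


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced-scale synthetic study shared across tests (deterministic)."""
    return synth.generate_cohort(synth.SimConfig.scaled(seed=7, factor=0.25))


@pytest.fixture(scope="session")
def small_summaries(small_cohort):
    """Processed per player-session summaries for the reduced cohort."""
    return pl.process_cohort(small_cohort)


@pytest.fixture(scope="session")
def exact_cal_summaries():
    """Summaries for a cohort under the exact-recovery preconditions:
    noise-free calibration stages (fitted thresholds equal planted ones)
    and bouts of at least 5 s (no boundary-leakage epochs).  Trace noise
    stays at its default."""
    cohort = synth.generate_cohort(
        synth.SimConfig.scaled(seed=9, factor=0.1, calib_noise_sd_n=0.0,
                               bout_min_s=5.0))
    return cohort, pl.process_cohort(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
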