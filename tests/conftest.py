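"""Shared fixtures.

The two expensive session fixtures run the full synthetic cohorts once and
are shared by the end-to-end and ablation tests.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from preictal.evaluation import (
    CohortConfig,
    ExperimentConfig,
    run_ablation,
    run_experiment,
)
from preictal.preprocess import Epoch
from preictal.synthetic import SynthSpec, generate_recording

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_epoch(data: np.ndarray, label: int = 0, fs: float = 256.0,
               subject: str = "s1", t0: float = 0.0) -> Epoch:
    data = np.asarray(data, dtype=float)
    return Epoch(
        data=data,
        label=label,
        subject_id=subject,
        t_start_s=t0,
        epoch_len_s=data.shape[1] / fs,
        fs=fs,
    )


@pytest.fixture(scope="session")
def small_recording():
    """A 4-channel recording with one annotated seizure (fast to generate)."""
    spec = SynthSpec(
        n_channels=4,
        duration_s=120.0,
        seizure_onsets_s=[100.0],
        seizure_duration_s=10.0,
        preictal_window_s=40.0,
        seed=7,
    )
    return generate_recording(spec)


@pytest.fixture(scope="session")
def strong_cohort_results():
    """Full model + ablation arms on the 8-subject strong-signal cohort.

    Preictal epochs carry doubled alpha amplitude and a shifted
    inter-channel correlation decay relative to baseline.
    """
    cfg = ExperimentConfig(cohort=CohortConfig(n_subjects=8), seed=0)
    return run_ablation(cfg, arms=("backbone", "single-svm", "no-vote", "seg20"))


@pytest.fixture(scope="session")
def no_signal_result():
    """Cohort whose preictal state is statistically identical to baseline."""
    cfg = ExperimentConfig(
        cohort=CohortConfig(n_subjects=8, alpha_gain=1.0, rho_preictal=0.3),
        seed=0,
    )
    return run_experiment(cfg)
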