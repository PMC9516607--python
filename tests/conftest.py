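import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from luxate import (
    ALL_LABELS,
    CalibrationPose,
    ClassProfile,
    DatasetSpec,
    RecordingMeta,
    ToothFrameRecording,
    balanced_counts,
    generate_dataset,
    generate_recording,
)


@pytest.fixture(scope="session")
def quiet_profile() -> ClassProfile:
    """Deterministic profile: no noise, no jitter, fixed duration."""
    return ClassProfile(
        duration_mean=30.0,
        duration_sd=0.0,
        luxation_freq=0.5,
        amp_jitter_sd=0.0,
        noise_sd_force=0.0,
        noise_sd_torque=0.0,
        noise_sd_angle=0.0,
    )


@pytest.fixture(scope="session")
def clean_recording(quiet_profile):
    """Noise-free recording with identity calibration, with ground truth."""
    return generate_recording(
        quiet_profile,
        ALL_LABELS[0],
        seed=0,
        calibration=CalibrationPose.identity(),
        with_truth=True,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """16 noisy recordings, 2 per label."""
    spec = DatasetSpec(counts=balanced_counts(16), seed=3)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def medium_dataset():
    """32 noisy recordings, 4 per label — enough for 2-fold CV."""
    spec = DatasetSpec(counts=balanced_counts(32), seed=5)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def default_dataset():
    """The full default dataset: 110 recordings over 8 labels."""
    return generate_dataset(DatasetSpec(seed=0))


def _make_tooth_frame_recording(
    t: np.ndarray,
    force=None,
    torque=None,
    disp=None,
    theta=None,
    omega=None,
    fs: float = 100.0,
) -> ToothFrameRecording:
    """Assemble a ToothFrameRecording with zero-filled defaults."""
    n = len(t)
    zeros = np.zeros((3, n))

    def pick(x):
        return zeros.copy() if x is None else np.asarray(x, dtype=float)

    return ToothFrameRecording(
        t=t,
        force=pick(force),
        torque=pick(torque),
        disp=pick(disp),
        theta=pick(theta),
        omega=pick(omega),
        meta=RecordingMeta(experiment_id="test-000", label=ALL_LABELS[0]),
        fs=fs,
    )


@pytest.fixture(scope="session")
def make_tooth_frame_recording():
    """Factory fixture for hand-built tooth-frame recordings."""
    return _make_tooth_frame_recording
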