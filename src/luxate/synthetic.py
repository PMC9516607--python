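"""Class-conditional synthetic tooth-removal recordings.

Real extraction recordings are dominated by luxation: slow (well below
2 Hz) rocking torques about the buccolingual (X) and longitudinal (Z)
axes, buccoversion/linguoversion torque about Y, and a terminal
extrusion pull along -Z once the tooth is mobile. The generator
emulates that structure with amplitude-enveloped sinusoidal torque and
rotation bursts, class-specific amplitudes and durations, and a
negative-Z force ramp over the final 20% of each recording.

Default class profiles encode the qualitative clinical ordering the
analysis relies on: molars receive larger and longer torque work than
bicuspids, cuspids and incisors (in that order), lower-jaw dorsal teeth
see higher average torques than their upper-jaw counterparts, rotation
about the long axis dominates for single-rooted anterior teeth while
buccolingual rocking dominates for multi-rooted posterior teeth, and
incisor average combined torques stay low (well under 6 Nm). No claim
of quantitative biomechanical fidelity is made.

Signals are emitted in the *sensor* frame, pre-transformed by a random
rigid calibration pose, so the preprocessing stage performs the same
frame recovery it would on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    ALL_LABELS,
    CalibrationPose,
    Jaw,
    RawRecording,
    RecordingMeta,
    ToothClass,
    ToothLabel,
    wxyz_from_rotation,
)

FT_RATE = 20.0  # Hz, force/torque sensor
KIN_RATE = 100.0  # Hz, robot-arm pose stream

# fixed per-channel phases (rad) so channels are not trivially collinear
_PHASES = {
    "Tx": np.pi / 6,
    "Ty": 0.0,
    "Tz": np.pi / 3,
    "Fx": np.pi / 4,
    "Fy": np.pi / 2,
    "Fz": np.pi / 5,
    # rotation channels start at zero so the relative orientation at t=0
    # is the calibration pose itself
    "thx": 0.0,
    "thy": 0.0,
    "thz": np.pi,
}


class GenerationError(RuntimeError):
    """Raised when a profile cannot yield a valid recording."""


@dataclass
class ClassProfile:
    """Stochastic signal model for one tooth label.

    Amplitudes are the mid-recording values of the luxation envelope;
    ``envelope_growth`` makes bursts grow as the tooth loosens
    (0 keeps the amplitude constant). ``torque_bias_X`` adds a constant
    mesial(+)/distal(-) angulation torque, the main jaw signature.
    ``amp_jitter_sd`` is the log-scale sd of a per-recording amplitude
    multiplier emulating tooth-to-tooth variability.
    """

    duration_mean: float = 30.0  # s
    duration_sd: float = 3.0  # s
    luxation_freq: float = 0.8  # Hz, << the 10 Hz Nyquist of the FT stream
    torque_amp_X: float = 0.5  # Nm
    torque_amp_Y: float = 2.0  # Nm
    torque_amp_Z: float = 1.0  # Nm
    torque_bias_X: float = 0.0  # Nm
    force_amp_X: float = 5.0  # N
    force_amp_Y: float = 5.0  # N
    force_amp_Z: float = 3.0  # N
    extrusion_peak: float = 20.0  # N, magnitude of the final -Z pull
    rotation_amp_X: float = 1.0  # deg
    rotation_amp_Y: float = 5.0  # deg
    rotation_amp_Z: float = 10.0  # deg
    envelope_growth: float = 0.7  # dimensionless
    amp_jitter_sd: float = 0.08  # log-scale sd
    noise_sd_force: float = 0.3  # N
    noise_sd_torque: float = 0.08  # Nm
    noise_sd_angle: float = 0.3  # deg

    def __post_init__(self) -> None:
        amps = (
            self.torque_amp_X,
            self.torque_amp_Y,
            self.torque_amp_Z,
            self.force_amp_X,
            self.force_amp_Y,
            self.force_amp_Z,
            self.extrusion_peak,
            self.rotation_amp_X,
            self.rotation_amp_Y,
            self.rotation_amp_Z,
            self.noise_sd_force,
            self.noise_sd_torque,
            self.noise_sd_angle,
            self.amp_jitter_sd,
            self.duration_sd,
        )
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes and noise levels must be non-negative")
        if self.duration_mean <= 0:
            raise ValueError("duration_mean must be positive")
        if not 0 < self.luxation_freq < 10.0:
            raise ValueError("luxation_freq must lie in (0, 10) Hz")


# class-level scales: incisor, cuspid, bicuspid, molar
_TORQUE_SCALE = {
    ToothClass.INCISOR: 1.5,
    ToothClass.CUSPID: 3.0,
    ToothClass.BICUSPID: 5.0,
    ToothClass.MOLAR: 7.5,
}
_DURATION = {
    ToothClass.INCISOR: 20.0,
    ToothClass.CUSPID: 25.0,
    ToothClass.BICUSPID: 30.0,
    ToothClass.MOLAR: 35.0,
}
_FORCE_SCALE = {
    ToothClass.INCISOR: 5.0,
    ToothClass.CUSPID: 8.0,
    ToothClass.BICUSPID: 12.0,
    ToothClass.MOLAR: 15.0,
}
_EXTRUSION = {
    ToothClass.INCISOR: 20.0,
    ToothClass.CUSPID: 30.0,
    ToothClass.BICUSPID: 40.0,
    ToothClass.MOLAR: 50.0,
}
# anterior teeth rotate about the long axis; posterior teeth are rocked
# buccolingually
_ROT_Y = {
    ToothClass.INCISOR: 5.0,
    ToothClass.CUSPID: 8.0,
    ToothClass.BICUSPID: 15.0,
    ToothClass.MOLAR: 20.0,
}
_ROT_Z = {
    ToothClass.INCISOR: 15.0,
    ToothClass.CUSPID: 20.0,
    ToothClass.BICUSPID: 8.0,
    ToothClass.MOLAR: 5.0,
}


def default_profiles() -> dict[ToothLabel, ClassProfile]:
    """Default per-label profiles encoding the clinical orderings above."""
    profiles: dict[ToothLabel, ClassProfile] = {}
    for label in ALL_LABELS:
        tc = label.tooth_class
        lower = label.jaw is Jaw.LOWER
        jaw_amp = 1.3 if lower else 1.0  # lower-jaw dorsal teeth torque harder
        s = _TORQUE_SCALE[tc] * jaw_amp
        profiles[label] = ClassProfile(
            duration_mean=_DURATION[tc],
            duration_sd=2.0,
            luxation_freq=1.0 if lower else 0.6,
            torque_amp_X=0.25 * s,
            torque_amp_Y=s,
            torque_amp_Z=0.6 * s,
            torque_bias_X=(0.25 if lower else -0.25) * s,
            force_amp_X=_FORCE_SCALE[tc],
            force_amp_Y=0.8 * _FORCE_SCALE[tc],
            force_amp_Z=0.5 * _FORCE_SCALE[tc],
            extrusion_peak=_EXTRUSION[tc] * (1.2 if lower else 1.0),
            rotation_amp_X=2.0,
            rotation_amp_Y=_ROT_Y[tc],
            rotation_amp_Z=_ROT_Z[tc],
        )
    return profiles


@dataclass
class DatasetSpec:
    """Composition of a synthetic dataset.

    ``counts`` maps each label to its number of recordings; the default
    is a near-balanced partition of 110 experiments over the 8 labels.
    ``profiles`` overrides the default class profiles per label.
    """

    counts: dict[ToothLabel, int] | None = None
    seed: int = 0
    profiles: dict[ToothLabel, ClassProfile] = field(default_factory=dict)

    def resolved_counts(self) -> dict[ToothLabel, int]:
        counts = self.counts if self.counts is not None else balanced_counts(110)
        if any(c < 0 for c in counts.values()):
            raise ValueError("per-label counts must be non-negative")
        if sum(counts.values()) <= 0:
            raise ValueError("total recording count must be positive")
        return counts

    def resolved_profiles(self) -> dict[ToothLabel, ClassProfile]:
        profiles = default_profiles()
        profiles.update(self.profiles)
        return profiles


def balanced_counts(total: int) -> dict[ToothLabel, int]:
    """Partition ``total`` recordings as evenly as possible over 8 labels."""
    if total <= 0:
        raise ValueError("total must be positive")
    base, rem = divmod(total, len(ALL_LABELS))
    return {lab: base + (1 if i < rem else 0) for i, lab in enumerate(ALL_LABELS)}


def _random_calibration(rng: np.random.Generator) -> CalibrationPose:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return CalibrationPose(origin=rng.normal(scale=0.05, size=3), orientation=q)


def _continuous_sign(q: np.ndarray) -> np.ndarray:
    """Flip quaternion signs so consecutive rows stay in the same cover."""
    q = q.copy()
    flips = np.cumsum(np.sum(q[1:] * q[:-1], axis=1) < 0) % 2
    q[1:][flips == 1] *= -1
    return q


def generate_recording(
    profile: ClassProfile,
    label: ToothLabel,
    seed: int | np.random.Generator = 0,
    experiment_id: str = "exp-000",
    calibration: CalibrationPose | None = None,
    with_truth: bool = False,
) -> RawRecording:
    """Generate one dual-rate recording for ``label`` under ``profile``.

    The tooth-frame ground truth is built first, then pushed into the
    sensor frame through the (random unless given) calibration pose:
    vectors by the calibration rotation, positions by rotation plus the
    calibrated origin, orientations by quaternion composition. With
    ``with_truth=True`` the noise-free tooth-frame signals are attached
    to the returned recording for verification.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    duration = profile.duration_mean + profile.duration_sd * rng.standard_normal()
    n_ft = int(round(duration * FT_RATE))
    if duration <= 0 or n_ft < 2:
        raise GenerationError(f"sampled duration {duration:.3f}s yields no usable samples")
    duration = n_ft / FT_RATE
    t_ft = np.arange(n_ft) / FT_RATE
    n_kin = n_ft * int(KIN_RATE / FT_RATE)
    t_kin = np.arange(n_kin) / KIN_RATE

    g_torque = float(np.exp(rng.normal(0.0, profile.amp_jitter_sd)))
    g_force = float(np.exp(rng.normal(0.0, profile.amp_jitter_sd)))

    w = 2 * np.pi * profile.luxation_freq

    def env(t: np.ndarray) -> np.ndarray:
        return 1.0 + profile.envelope_growth * (t / duration - 0.5)

    def ramp(t: np.ndarray) -> np.ndarray:
        return np.clip((t - 0.8 * duration) / (0.2 * duration), 0.0, 1.0)

    def torque_truth(t: np.ndarray) -> np.ndarray:
        e = env(t)
        return np.column_stack(
            [
                profile.torque_bias_X
                + profile.torque_amp_X * g_torque * e * np.sin(w * t + _PHASES["Tx"]),
                profile.torque_amp_Y * g_torque * e * np.sin(w * t + _PHASES["Ty"]),
                profile.torque_amp_Z * g_torque * e * np.sin(w * t + _PHASES["Tz"]),
            ]
        )

    def force_truth(t: np.ndarray) -> np.ndarray:
        e = env(t)
        f = np.column_stack(
            [
                profile.force_amp_X * g_force * e * np.sin(w * t + _PHASES["Fx"]),
                profile.force_amp_Y * g_force * e * np.sin(w * t + _PHASES["Fy"]),
                profile.force_amp_Z * g_force * e * np.sin(w * t + _PHASES["Fz"]),
            ]
        )
        f[:, 2] -= profile.extrusion_peak * g_force * ramp(t)
        return f

    def theta_truth(t: np.ndarray) -> np.ndarray:
        e = env(t)
        return np.column_stack(
            [
                profile.rotation_amp_X * g_torque * e * np.sin(w * t + _PHASES["thx"]),
                profile.rotation_amp_Y * g_torque * e * np.sin(w * t + _PHASES["thy"]),
                profile.rotation_amp_Z * g_torque * e * np.sin(w * t + _PHASES["thz"]),
            ]
        )

    def disp_truth(t: np.ndarray, theta: np.ndarray) -> np.ndarray:
        # crown excursion roughly proportional to angulation, plus the
        # extrusion travel out of the socket (~2 mm at a 50 N pull)
        d = 2e-4 * theta
        d[:, 2] -= 4e-5 * profile.extrusion_peak * g_force * ramp(t)
        return d

    ft_force = force_truth(t_ft)
    ft_torque = torque_truth(t_ft)
    theta_kin = theta_truth(t_kin)
    disp_kin = disp_truth(t_kin, theta_kin)

    noisy_force = ft_force + rng.normal(0.0, profile.noise_sd_force, ft_force.shape)
    noisy_torque = ft_torque + rng.normal(0.0, profile.noise_sd_torque, ft_torque.shape)
    noisy_theta = theta_kin + rng.normal(0.0, profile.noise_sd_angle, theta_kin.shape)
    # position noise scales with angle noise through the same
    # crown-excursion factor, so a noise-free profile is exactly clean
    noisy_disp = disp_kin + rng.normal(0.0, 2e-4 * profile.noise_sd_angle, disp_kin.shape)

    calib = calibration if calibration is not None else _random_calibration(rng)
    r_cal = calib.rotation

    sensor_force = r_cal.apply(noisy_force)
    sensor_torque = r_cal.apply(noisy_torque)
    sensor_pos = calib.origin + r_cal.apply(noisy_disp)
    rel_rot = Rotation.from_rotvec(np.deg2rad(noisy_theta))
    sensor_quat = _continuous_sign(wxyz_from_rotation(r_cal * rel_rot))

    truth = None
    if with_truth:
        truth = {
            "t_ft": t_ft,
            "force": ft_force,
            "torque": ft_torque,
            "t_kin": t_kin,
            "theta": theta_kin,
            "disp": disp_kin,
        }

    return RawRecording(
        ft_t=t_ft,
        ft_force=sensor_force,
        ft_torque=sensor_torque,
        kin_t=t_kin,
        kin_pos=sensor_pos,
        kin_quat=sensor_quat,
        calibration=calib,
        meta=RecordingMeta(experiment_id=experiment_id, label=label),
        truth=truth,
    )


def generate_dataset(spec: DatasetSpec | None = None) -> list[RawRecording]:
    """Generate the full dataset described by ``spec`` (default: 110 recordings).

    Each recording gets an independent child seed spawned from
    ``spec.seed``, so the dataset is reproducible as a whole and any
    single recording can be regenerated in isolation.
    """
    spec = spec if spec is not None else DatasetSpec()
    counts = spec.resolved_counts()
    profiles = spec.resolved_profiles()
    total = sum(counts.values())
    children = np.random.SeedSequence(spec.seed).spawn(total)

    recordings: list[RawRecording] = []
    i = 0
    for label in ALL_LABELS:
        for _ in range(counts.get(label, 0)):
            rng = np.random.default_rng(children[i])
            recordings.append(
                generate_recording(
                    profiles[label], label, seed=rng, experiment_id=f"exp-{i:03d}"
                )
            )
            i += 1
    return recordings
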