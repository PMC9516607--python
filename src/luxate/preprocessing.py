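"""Raw dual-rate sensor streams -> single-rate tooth-frame signals.

Stages, in order: optional automatic trimming of quiet lead-in/out,
rigid transformation into the clinical tooth frame via the calibration
pose, zero-phase low-pass Butterworth filtering, FFT upsampling of the
20 Hz force/torque stream to the 100 Hz kinematic rate, and central-
difference rotational velocity.

Rotations are decomposed as rotation vectors (axis-angle times angle,
reported per axis in degrees) rather than Euler angles, avoiding
ordering and gimbal ambiguities for the small luxation angles involved.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.spatial.transform import Rotation

from .core import (
    RawRecording,
    ToothFrameRecording,
    check_unit_quaternions,
    rotation_from_wxyz,
)


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters.

    Cutoffs are in Hz and apply to the stream's own rate (force/torque
    at ~20 Hz, kinematics at ~100 Hz); ``None`` disables filtering for
    that stream. Luxation content sits below ~2 Hz, so the defaults
    (4th order, 5 and 10 Hz) remove sensor noise without touching it;
    zero-phase application keeps force and motion time-aligned.
    ``trim_threshold`` (N + Nm combined magnitude) enables automatic
    removal of quiet lead-in/lead-out when positive.
    """

    force_cutoff_hz: float | None = 5.0
    kin_cutoff_hz: float | None = 10.0
    filter_order: int = 4
    trim_threshold: float = 0.0


def transform_to_tooth_frame(
    raw: RawRecording,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, Rotation]:
    """Re-express raw sensor-frame streams in the clinical tooth frame.

    Forces and torques are rotated by the inverse calibration
    orientation; positions are first translated by the calibrated
    origin, then rotated, giving displacement from the tooth; the
    orientation stream becomes the rotation relative to the calibrated
    orientation. Rotation preserves Euclidean norms, so force/torque
    magnitudes are untouched.

    Returns ``(force (3,n), torque (3,n), disp (3,m), rel_rot)``.
    """
    check_unit_quaternions(raw.kin_quat, what="kinematic quaternion")
    r_cal_inv = raw.calibration.rotation.inv()
    force = r_cal_inv.apply(raw.ft_force).T
    torque = r_cal_inv.apply(raw.ft_torque).T
    disp = r_cal_inv.apply(raw.kin_pos - raw.calibration.origin).T
    rel_rot = r_cal_inv * rotation_from_wxyz(raw.kin_quat)
    return force, torque, disp, rel_rot


def rotation_angles(rel: Rotation | np.ndarray) -> np.ndarray:
    """Per-axis rotation angles (deg) of a relative-orientation series.

    Each orientation is decomposed as a rotation vector; the series is
    kept sign-consistent (quaternions flipped into one cover of SO(3))
    so the traces are continuous in time.
    """
    if isinstance(rel, Rotation):
        quats = np.atleast_2d(rel.as_quat())
    else:
        quats = np.atleast_2d(np.asarray(rel, dtype=float))
    quats = quats.copy()
    flips = np.cumsum(np.sum(quats[1:] * quats[:-1], axis=1) < 0) % 2
    quats[1:][flips == 1] *= -1
    return np.rad2deg(Rotation.from_quat(quats).as_rotvec()).T


def lowpass_butterworth(
    x: np.ndarray, fs: float, cutoff: float, order: int = 4
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter along the last axis.

    Forward-backward application squares the magnitude response (gain
    1/2 at the cutoff instead of the single-pass 1/sqrt(2)) and cancels
    the phase shift, so feature timing is unshifted. Output length
    equals input length.
    """
    if order < 1:
        raise ValueError("filter order must be >= 1")
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2) = (0, {fs / 2:g}) Hz")
    x = np.asarray(x, dtype=float)
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    default_padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    padlen = min(default_padlen, x.shape[-1] - 1)
    return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def resample_fft(x: np.ndarray, fs_in: float = 20.0, fs_out: float = 100.0) -> np.ndarray:
    """Fourier-domain resampling along the last axis.

    Zero-pads (or truncates) the spectrum so the output has
    ``round(n * fs_out / fs_in)`` samples; the DC component — hence the
    signal mean — is preserved exactly.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] == 0:
        raise ValueError("cannot resample an empty signal")
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    n_out = int(round(x.shape[-1] * fs_out / fs_in))
    return sps.resample(x, n_out, axis=-1)


def auto_trim(raw: RawRecording, threshold: float) -> RawRecording:
    """Remove quiet lead-in/lead-out where ||F|| + ||T|| < threshold.

    Replaces the study protocol's manual trimming. A non-positive
    threshold is a no-op; if the whole recording is quiet it is
    returned unchanged with ``meta.extra['trim_warning'] = True``.
    """
    if threshold < 0:
        raise ValueError("trim threshold must be >= 0")
    if threshold == 0:
        return raw
    mag = np.linalg.norm(raw.ft_force, axis=1) + np.linalg.norm(raw.ft_torque, axis=1)
    active = np.flatnonzero(mag >= threshold)
    if active.size < 2:
        out = raw.copy()
        out.meta.extra["trim_warning"] = True
        return out
    t0, t1 = raw.ft_t[active[0]], raw.ft_t[active[-1]]
    ft_keep = slice(active[0], active[-1] + 1)
    kin_keep = (raw.kin_t >= t0 - 1e-12) & (raw.kin_t <= t1 + 1e-12)
    if kin_keep.sum() < 2:
        out = raw.copy()
        out.meta.extra["trim_warning"] = True
        return out
    return RawRecording(
        ft_t=raw.ft_t[ft_keep],
        ft_force=raw.ft_force[ft_keep],
        ft_torque=raw.ft_torque[ft_keep],
        kin_t=raw.kin_t[kin_keep],
        kin_pos=raw.kin_pos[kin_keep],
        kin_quat=raw.kin_quat[kin_keep],
        calibration=raw.calibration,
        meta=dataclasses.replace(raw.meta, extra=dict(raw.meta.extra)),
        truth=None,
    )


def _restrict_to_overlap(raw: RawRecording) -> RawRecording:
    t0, t1 = raw.overlap_window()
    ft_keep = (raw.ft_t >= t0 - 1e-12) & (raw.ft_t <= t1 + 1e-12)
    kin_keep = (raw.kin_t >= t0 - 1e-12) & (raw.kin_t <= t1 + 1e-12)
    if ft_keep.all() and kin_keep.all():
        return raw
    return RawRecording(
        ft_t=raw.ft_t[ft_keep],
        ft_force=raw.ft_force[ft_keep],
        ft_torque=raw.ft_torque[ft_keep],
        kin_t=raw.kin_t[kin_keep],
        kin_pos=raw.kin_pos[kin_keep],
        kin_quat=raw.kin_quat[kin_keep],
        calibration=raw.calibration,
        meta=raw.meta,
        truth=None,
    )


def _median_rate(t: np.ndarray) -> float:
    return 1.0 / float(np.median(np.diff(t)))


def preprocess(
    raw: RawRecording, config: PreprocessConfig | None = None
) -> ToothFrameRecording:
    """Full preprocessing of one raw recording.

    Order of operations: trim -> restrict to the common time window ->
    transform to the tooth frame -> rotation-vector angles -> zero-phase
    filtering (each stream at its own rate) -> rebase angles and
    displacement to zero at the first sample -> FFT-upsample the
    force/torque stream to the kinematic rate -> align the kinematic
    traces onto the upsampled clock by linear interpolation ->
    differentiate angles to rotational velocity (central differences).
    """
    config = config if config is not None else PreprocessConfig()
    raw = auto_trim(raw, config.trim_threshold)
    raw = _restrict_to_overlap(raw)

    force, torque, disp, rel_rot = transform_to_tooth_frame(raw)
    theta = rotation_angles(rel_rot)

    fs_ft = _median_rate(raw.ft_t)
    fs_kin = _median_rate(raw.kin_t)

    if config.force_cutoff_hz is not None:
        force = lowpass_butterworth(force, fs_ft, config.force_cutoff_hz, config.filter_order)
        torque = lowpass_butterworth(torque, fs_ft, config.force_cutoff_hz, config.filter_order)
    if config.kin_cutoff_hz is not None:
        theta = lowpass_butterworth(theta, fs_kin, config.kin_cutoff_hz, config.filter_order)
        disp = lowpass_butterworth(disp, fs_kin, config.kin_cutoff_hz, config.filter_order)

    # calibration alignment: traces start at exactly zero angle/offset
    theta = theta - theta[:, :1]
    disp = disp - disp[:, :1]

    n_out = int(round(force.shape[-1] * fs_kin / fs_ft))
    force = resample_fft(force, fs_ft, fs_kin)
    torque = resample_fft(torque, fs_ft, fs_kin)
    t_new = raw.ft_t[0] + np.arange(n_out) / fs_kin

    keep = (t_new >= raw.kin_t[0] - 1e-9) & (t_new <= raw.kin_t[-1] + 1e-9)
    t_new = t_new[keep]
    force = force[:, keep]
    torque = torque[:, keep]
    theta = np.vstack([np.interp(t_new, raw.kin_t, row) for row in theta])
    disp = np.vstack([np.interp(t_new, raw.kin_t, row) for row in disp])

    omega = np.gradient(theta, 1.0 / fs_kin, axis=1)

    return ToothFrameRecording(
        t=t_new,
        force=force,
        torque=torque,
        disp=disp,
        theta=theta,
        omega=omega,
        meta=raw.meta,
        fs=fs_kin,
    )
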