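"""Frame transformation, filtering, resampling and trimming."""

import dataclasses

import numpy as np
import pytest
from scipy.linalg import logm
from scipy.spatial.transform import Rotation

from luxate import (
    ALL_LABELS,
    CalibrationPose,
    ClassProfile,
    RawRecording,
    RecordingMeta,
    auto_trim,
    generate_recording,
    lowpass_butterworth,
    preprocess,
    resample_fft,
    rotation_angles,
    transform_to_tooth_frame,
)
from luxate.core import wxyz_from_rotation
from luxate.preprocessing import PreprocessConfig

NO_FILTER = PreprocessConfig(force_cutoff_hz=None, kin_cutoff_hz=None)


def _make_raw(calibration, ft_force=None, duration=2.0, quat_series=None, kin_pos=None):
    n = int(duration * 20)
    m = n * 5
    ft_t = np.arange(n) / 20.0
    kin_t = np.arange(m) / 100.0
    if ft_force is None:
        ft_force = np.zeros((n, 3))
    if quat_series is None:
        quat_series = np.tile([1.0, 0, 0, 0], (m, 1))
    if kin_pos is None:
        kin_pos = np.zeros((m, 3))
    return RawRecording(
        ft_t=ft_t,
        ft_force=ft_force,
        ft_torque=np.zeros((n, 3)),
        kin_t=kin_t,
        kin_pos=kin_pos,
        kin_quat=quat_series,
        calibration=calibration,
        meta=RecordingMeta("exp-000", ALL_LABELS[0]),
    )


class TestFrameTransform:
    def test_identity_calibration_is_identity(self):
        rng = np.random.default_rng(0)
        force = rng.normal(size=(40, 3))
        raw = _make_raw(CalibrationPose.identity(), ft_force=force)
        f, t, d, rel = transform_to_tooth_frame(raw)
        assert np.allclose(f.T, force, atol=1e-14)
        assert np.allclose(d, 0, atol=1e-14)
        assert np.allclose(rel.magnitude(), 0, atol=1e-12)

    def test_quarter_turn_about_z(self):
        """Calibration = +90 deg about Z; a sensor-frame force along +X
        is buccolingually -Y in the tooth frame (quaternion oracle
        q* v q evaluated symbolically: Rz(-90)(1,0,0) = (0,-1,0))."""
        rot = Rotation.from_euler("z", 90, degrees=True)
        calib = CalibrationPose(origin=np.zeros(3), orientation=wxyz_from_rotation(rot)[0])
        force = np.tile([1.0, 0.0, 0.0], (40, 1))
        raw = _make_raw(calib, ft_force=force)
        f, _, _, _ = transform_to_tooth_frame(raw)
        assert np.allclose(f.T, np.tile([0.0, -1.0, 0.0], (40, 1)), atol=1e-12)

    def test_rotation_is_isometry(self):
        rng = np.random.default_rng(1)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        calib = CalibrationPose(origin=rng.normal(size=3), orientation=q)
        force = rng.normal(size=(40, 3))
        raw = _make_raw(calib, ft_force=force)
        f, _, _, _ = transform_to_tooth_frame(raw)
        in_norms = np.linalg.norm(force, axis=1)
        out_norms = np.linalg.norm(f.T, axis=1)
        assert np.max(np.abs(out_norms - in_norms) / np.maximum(in_norms, 1e-300)) <= 1e-12

    def test_round_trip_through_inverse_pose(self):
        rng = np.random.default_rng(2)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        rot = Rotation.from_quat(np.roll(q, -1))
        calib = CalibrationPose(origin=rng.normal(size=3), orientation=q)
        inv = CalibrationPose(
            origin=-rot.inv().apply(calib.origin),
            orientation=wxyz_from_rotation(rot.inv())[0],
        )
        force = rng.normal(size=(40, 3))
        raw = _make_raw(calib, ft_force=force)
        f1, _, _, _ = transform_to_tooth_frame(raw)
        raw2 = _make_raw(inv, ft_force=f1.T)
        f2, _, _, _ = transform_to_tooth_frame(raw2)
        # applying the pose then its inverse restores the input
        raw3 = _make_raw(calib, ft_force=f2.T)
        f3, _, _, _ = transform_to_tooth_frame(raw3)
        assert np.allclose(f3.T, f1.T, atol=1e-12)


class TestRotationAngles:
    def test_identity_series_is_zero(self):
        quats = np.tile([0.0, 0.0, 0.0, 1.0], (50, 1))  # xyzw
        theta = rotation_angles(quats)
        assert np.allclose(theta, 0, atol=1e-12)

    def test_pure_rotation_about_y(self):
        rot = Rotation.from_euler("y", 10, degrees=True)
        theta = rotation_angles(np.tile(rot.as_quat(), (5, 1)))
        assert np.allclose(theta[:, 0], [0, 10, 0], atol=1e-9)

    def test_composed_rotation_matches_matrix_log_oracle(self):
        rot = Rotation.from_euler("y", 5, degrees=True) * Rotation.from_euler(
            "z", 5, degrees=True
        )
        theta = rotation_angles(np.atleast_2d(rot.as_quat()))[:, 0]
        log_r = logm(rot.as_matrix())
        oracle = np.rad2deg([log_r[2, 1], log_r[0, 2], log_r[1, 0]])
        assert np.max(np.abs(theta - np.real(oracle))) < 0.1

    def test_sign_continuity_across_quaternion_cover_flip(self):
        angles = np.linspace(0, 20, 200)[:, None]
        rots = Rotation.from_euler("y", angles, degrees=True)
        quats = rots.as_quat()
        quats[100:] *= -1  # same rotations, other cover
        theta = rotation_angles(quats)
        assert np.max(np.abs(np.diff(theta[1]))) < 0.2  # no jump


class TestButterworth:
    def test_dc_gain_is_one(self):
        x = np.full(500, 3.7)
        y = lowpass_butterworth(x, fs=100, cutoff=5)
        assert np.allclose(y, 3.7, atol=1e-9)

    def test_gain_at_cutoff_matches_analytic_magnitude(self):
        """Forward-backward application squares |H|; at the cutoff the
        single-pass gain is 1/sqrt(2), so the zero-phase gain is 1/2."""
        fs, fc = 100.0, 2.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * fc * t)
        y = lowpass_butterworth(x, fs=fs, cutoff=fc, order=4)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        amplitude = np.sqrt(2) * np.sqrt(np.mean(y[mid] ** 2))
        assert abs(amplitude - 0.5) / 0.5 < 0.02

    def test_attenuation_at_ten_times_cutoff(self):
        """|H(10 fc)| for order 4 is 1/sqrt(1+10^8) ~ -80 dB single-pass;
        even one pass must exceed 60 dB."""
        fs, fc = 100.0, 2.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * 10 * fc * t)
        y = lowpass_butterworth(x, fs=fs, cutoff=fc, order=4)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        amplitude = np.sqrt(2) * np.sqrt(np.mean(y[mid] ** 2))
        assert amplitude < 10 ** (-60 / 20)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=400)
        y = rng.normal(size=400)
        a, b = 2.5, -1.25
        lhs = lowpass_butterworth(a * x + b * y, fs=100, cutoff=5)
        rhs = a * lowpass_butterworth(x, fs=100, cutoff=5) + b * lowpass_butterworth(
            y, fs=100, cutoff=5
        )
        assert np.max(np.abs(lhs - rhs)) < 1e-9

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            lowpass_butterworth(np.zeros(100), fs=20, cutoff=10)
        with pytest.raises(ValueError):
            lowpass_butterworth(np.zeros(100), fs=20, cutoff=5, order=0)


class TestResample:
    def test_constant_preserved_and_length_scaled(self):
        x = np.full(40, 2.5)
        y = resample_fft(x, 20, 100)
        assert len(y) == 200
        assert np.allclose(y, 2.5, atol=1e-12)

    def test_band_limited_sinusoid_matches_analytic(self):
        """2 Hz sinusoid over an integer number of periods upsampled
        20 -> 100 Hz equals the analytic 100 Hz samples."""
        f = 2.0
        t20 = np.arange(0, 5, 1 / 20)  # 10 full periods
        x = np.sin(2 * np.pi * f * t20)
        y = resample_fft(x, 20, 100)
        t100 = np.arange(len(y)) / 100.0
        expected = np.sin(2 * np.pi * f * t100)
        rms = np.sqrt(np.mean((y - expected) ** 2))
        assert rms < 1e-6

    def test_mean_preserved(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=80) + 3.0
        y = resample_fft(x, 20, 100)
        assert abs(y.mean() - x.mean()) < 1e-9

    def test_energy_preserved_for_band_limited_signal(self):
        t20 = np.arange(0, 5, 1 / 20)
        x = np.sin(2 * np.pi * 2.0 * t20) + 0.5 * np.cos(2 * np.pi * 1.0 * t20)
        y = resample_fft(x, 20, 100)
        assert abs(np.mean(y**2) - np.mean(x**2)) / np.mean(x**2) < 1e-6

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            resample_fft(np.array([]), 20, 100)


class TestAutoTrim:
    def _padded_recording(self):
        n_active = 40
        pad = 20  # 1 s of silence at 20 Hz
        n = pad + n_active + pad
        force = np.zeros((n, 3))
        force[pad : pad + n_active, 0] = 5.0
        return _make_raw(CalibrationPose.identity(), ft_force=force, duration=n / 20.0)

    def test_quiet_edges_removed(self):
        raw = self._padded_recording()
        trimmed = auto_trim(raw, threshold=0.1)
        assert len(trimmed.ft_t) == 40
        assert np.all(np.linalg.norm(trimmed.ft_force, axis=1) > 0.1)
        # kinematic stream restricted to the same window
        assert trimmed.kin_t[0] >= trimmed.ft_t[0] - 1e-12
        assert trimmed.kin_t[-1] <= trimmed.ft_t[-1] + 1e-12

    def test_zero_threshold_is_noop(self):
        raw = self._padded_recording()
        trimmed = auto_trim(raw, threshold=0.0)
        assert trimmed is raw

    def test_all_quiet_recording_returned_with_warning_flag(self):
        raw = _make_raw(CalibrationPose.identity())
        trimmed = auto_trim(raw, threshold=0.1)
        assert len(trimmed.ft_t) == len(raw.ft_t)
        assert trimmed.meta.extra.get("trim_warning") is True


class TestPreprocess:
    def test_round_trip_recovers_generator_truth(self, clean_recording):
        """Noise-free recording, identity calibration, filters off: the
        preprocessed traces equal the generator's tooth-frame truth."""
        proc = preprocess(clean_recording, NO_FILTER)
        truth = clean_recording.truth
        n = len(proc.t)
        for arr, key in ((proc.theta, "theta"), (proc.disp, "disp")):
            expected = truth[key][:n].T
            rms = np.sqrt(np.mean((arr - expected) ** 2))
            assert rms < 1e-6, key
        # force/torque pass through FFT upsampling; compare on the
        # common 20 Hz samples where no interpolation is involved
        ft_n = len(truth["t_ft"])
        idx = np.arange(0, n, 5)
        for arr, key in ((proc.force, "force"), (proc.torque, "torque")):
            expected = truth[key][: len(idx)].T
            got = arr[:, idx]
            rms = np.sqrt(np.mean((got - expected[:, : got.shape[1]]) ** 2))
            assert rms < 1e-6, key

    def test_deterministic(self, clean_recording):
        a = preprocess(clean_recording)
        b = preprocess(clean_recording)
        assert np.array_equal(a.force, b.force)
        assert np.array_equal(a.theta, b.theta)

    def test_partial_overlap_restricts_window(self):
        n, m = 100, 300  # ft covers 5 s, kin covers 3 s
        raw = RawRecording(
            ft_t=np.arange(n) / 20.0,
            ft_force=np.zeros((n, 3)),
            ft_torque=np.zeros((n, 3)),
            kin_t=np.arange(m) / 100.0,
            kin_pos=np.zeros((m, 3)),
            kin_quat=np.tile([1.0, 0, 0, 0], (m, 1)),
            calibration=CalibrationPose.identity(),
            meta=RecordingMeta("exp-000", ALL_LABELS[0]),
        )
        proc = preprocess(raw, NO_FILTER)
        assert proc.t[-1] <= (m - 1) / 100.0 + 1e-9

    def test_output_has_uniform_shared_time_base(self, clean_recording):
        proc = preprocess(clean_recording)
        steps = np.diff(proc.t)
        assert np.max(np.abs(steps - steps[0])) <= 1e-9
        n = len(proc.t)
        for arr in (proc.force, proc.torque, proc.disp, proc.theta, proc.omega):
            assert arr.shape == (3, n)

    def test_calibration_alignment_zeroes_initial_pose(self, small_dataset):
        proc = preprocess(small_dataset[0])
        assert np.allclose(proc.theta[:, 0], 0, atol=1e-12)
        assert np.allclose(proc.disp[:, 0], 0, atol=1e-12)
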