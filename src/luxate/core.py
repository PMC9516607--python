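"""Domain types shared by every stage of the tooth-removal analysis pipeline.

The label taxonomy groups teeth into four clinical classes per jaw
(incisors, cuspids, bicuspids, molars), giving eight labels in total.
All signals are ultimately expressed in the *tooth frame*: a right-handed
orthonormal frame anchored at the tooth with X along the buccolingual
direction (buccal positive), Y along the mesiodistal direction (mesial
positive) and Z along the longitudinal tooth axis (intrusion positive,
extrusion negative).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Any, Mapping

import numpy as np
from scipy.spatial.transform import Rotation


class Jaw(str, Enum):
    """Upper or lower jaw."""

    UPPER = "U"
    LOWER = "L"


class ToothClass(IntEnum):
    """Tooth classes ordered along the dental arch, front to back."""

    INCISOR = 0
    CUSPID = 1
    BICUSPID = 2
    MOLAR = 3


#: FDI-style position codes used in the serialized label strings.
_CLASS_POSITIONS: dict[ToothClass, str] = {
    ToothClass.INCISOR: "1/2",
    ToothClass.CUSPID: "3",
    ToothClass.BICUSPID: "4/5",
    ToothClass.MOLAR: "6/7",
}
_POSITIONS_CLASS = {v: k for k, v in _CLASS_POSITIONS.items()}


@dataclass(frozen=True)
class ToothLabel:
    """One of the eight jaw x tooth-class labels.

    Serialized as e.g. ``"U1/2"`` (upper incisors) or ``"L6/7"``
    (lower molars).
    """

    jaw: Jaw
    tooth_class: ToothClass

    @property
    def code(self) -> str:
        return f"{self.jaw.value}{_CLASS_POSITIONS[self.tooth_class]}"

    @classmethod
    def from_code(cls, code: str) -> "ToothLabel":
        code = code.strip()
        if not code or code[0] not in ("U", "L"):
            raise ValueError(f"invalid tooth label code: {code!r}")
        positions = code[1:]
        if positions not in _POSITIONS_CLASS:
            raise ValueError(f"invalid tooth label code: {code!r}")
        return cls(Jaw(code[0]), _POSITIONS_CLASS[positions])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


#: Canonical label order: upper jaw front-to-back, then lower jaw.
ALL_LABELS: tuple[ToothLabel, ...] = tuple(
    ToothLabel(jaw, tc) for jaw in (Jaw.UPPER, Jaw.LOWER) for tc in ToothClass
)
LABEL_CODES: tuple[str, ...] = tuple(lab.code for lab in ALL_LABELS)


def same_jaw(a: ToothLabel, b: ToothLabel) -> bool:
    """True iff both labels belong to the same (upper/lower) jaw."""
    return a.jaw == b.jaw


def neighbor_of(a: ToothLabel, b: ToothLabel) -> bool:
    """True iff ``a`` and ``b`` are neighboring tooth classes.

    Neighborhood is defined within a jaw only: the class ranks
    (incisor < cuspid < bicuspid < molar) must differ by exactly one.
    A label is not its own neighbor, and cross-jaw pairs are never
    neighbors (cross-jaw adjacency has no clinical meaning for the
    extraction movements analysed here).
    """
    if not same_jaw(a, b):
        return False
    return abs(int(a.tooth_class) - int(b.tooth_class)) == 1


# ---------------------------------------------------------------------------
# Tooth-frame sign conventions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToothFrameConvention:
    """Sign semantics of the clinical tooth frame.

    ``translation_directions`` names the positive/negative directions of
    forces, displacements and positions along each axis;
    ``rotation_directions`` names rotations (and torques) *about* each
    axis. The frame is right-handed and orthonormal; every downstream
    sign (feature directions, generator conventions) derives from this
    single object.
    """

    translation_directions: Mapping[tuple[str, str], str]
    rotation_directions: Mapping[tuple[str, str], str]

    def direction(self, kind: str, axis: str, sign: str) -> str:
        table = (
            self.rotation_directions
            if kind == "rotation"
            else self.translation_directions
        )
        return table[(axis, sign)]


TOOTH_FRAME = ToothFrameConvention(
    translation_directions={
        ("X", "+"): "buccal",
        ("X", "-"): "lingual/palatal",
        ("Y", "+"): "mesial",
        ("Y", "-"): "distal",
        ("Z", "+"): "intrusion",
        ("Z", "-"): "extrusion",
    },
    rotation_directions={
        ("X", "+"): "mesial angulation",
        ("X", "-"): "distal angulation",
        ("Y", "+"): "buccoversion",
        ("Y", "-"): "linguoversion",
        ("Z", "+"): "mesiobuccal rotation",
        ("Z", "-"): "mesiopalatal/lingual rotation",
    },
)


# ---------------------------------------------------------------------------
# Quaternion helpers (scalar-first storage, scipy Rotation internally)
# ---------------------------------------------------------------------------

QUAT_TOL = 1e-6


def rotation_from_wxyz(q: np.ndarray) -> Rotation:
    """Build a scipy Rotation from scalar-first quaternion row(s)."""
    q = np.asarray(q, dtype=float)
    return Rotation.from_quat(np.roll(q, -1, axis=-1))


def wxyz_from_rotation(rot: Rotation) -> np.ndarray:
    """Scalar-first quaternion array from a scipy Rotation."""
    return np.roll(np.atleast_2d(rot.as_quat()), 1, axis=-1)


def check_unit_quaternions(q: np.ndarray, tol: float = QUAT_TOL, what: str = "quaternion") -> None:
    norms = np.linalg.norm(np.atleast_2d(np.asarray(q, dtype=float)), axis=-1)
    bad = np.flatnonzero(np.abs(norms - 1.0) > tol)
    if bad.size:
        raise ValueError(
            f"{what} norm deviates from 1 beyond {tol:g} at row {bad[0]} "
            f"(norm={norms[bad[0]]:.6g})"
        )


# ---------------------------------------------------------------------------
# Recording containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationPose:
    """Pose of the tooth frame in the sensor/robot frame.

    Acquired once just before each extraction; defines where the tooth
    frame sits so that raw sensor-frame streams can be re-expressed in
    clinically meaningful axes.
    """

    origin: np.ndarray  # (3,) metres
    orientation: np.ndarray  # (4,) unit quaternion, scalar first

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(
            self, "orientation", np.asarray(self.orientation, dtype=float).reshape(4)
        )
        check_unit_quaternions(self.orientation, what="calibration orientation")

    @property
    def rotation(self) -> Rotation:
        return rotation_from_wxyz(self.orientation)

    @classmethod
    def identity(cls) -> "CalibrationPose":
        return cls(origin=np.zeros(3), orientation=np.array([1.0, 0.0, 0.0, 0.0]))


@dataclass
class RecordingMeta:
    """Identity and provenance of a single extraction experiment."""

    experiment_id: str
    label: ToothLabel
    success: bool = True
    extra: dict[str, Any] = field(default_factory=dict)


@dataclass
class RawRecording:
    """Dual-rate sensor streams for one tooth-removal experiment.

    ``ft_t``/``ft_force``/``ft_torque`` hold the force/torque sensor
    stream (nominal 20 Hz, sensor frame, N and Nm). ``kin_t``/
    ``kin_pos``/``kin_quat`` hold the robot-arm pose stream (nominal
    100 Hz; position in metres, orientation as a scalar-first unit
    quaternion). ``truth``, when present, carries the noise-free
    tooth-frame signals a synthetic generator produced; it is never
    serialized and exists only for verification.
    """

    ft_t: np.ndarray  # (n,)
    ft_force: np.ndarray  # (n, 3)
    ft_torque: np.ndarray  # (n, 3)
    kin_t: np.ndarray  # (m,)
    kin_pos: np.ndarray  # (m, 3)
    kin_quat: np.ndarray  # (m, 4) scalar first
    calibration: CalibrationPose
    meta: RecordingMeta
    truth: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.ft_t = np.asarray(self.ft_t, dtype=float).ravel()
        self.kin_t = np.asarray(self.kin_t, dtype=float).ravel()
        self.ft_force = np.asarray(self.ft_force, dtype=float).reshape(len(self.ft_t), 3)
        self.ft_torque = np.asarray(self.ft_torque, dtype=float).reshape(len(self.ft_t), 3)
        self.kin_pos = np.asarray(self.kin_pos, dtype=float).reshape(len(self.kin_t), 3)
        self.kin_quat = np.asarray(self.kin_quat, dtype=float).reshape(len(self.kin_t), 4)
        self.validate()

    def validate(self) -> None:
        for name, t in (("ft", self.ft_t), ("kin", self.kin_t)):
            if t.size < 2:
                raise ValueError(f"{name} stream needs at least 2 samples")
            steps = np.diff(t)
            if np.any(steps <= 0):
                row = int(np.flatnonzero(steps <= 0)[0]) + 1
                raise ValueError(f"{name} timestamps not strictly increasing at row {row}")
        check_unit_quaternions(self.kin_quat, what="kinematic quaternion")
        if self.overlap_window()[1] <= self.overlap_window()[0]:
            raise ValueError("force/torque and kinematic streams do not overlap in time")

    def overlap_window(self) -> tuple[float, float]:
        return (
            max(self.ft_t[0], self.kin_t[0]),
            min(self.ft_t[-1], self.kin_t[-1]),
        )

    def copy(self) -> "RawRecording":
        return RawRecording(
            ft_t=self.ft_t.copy(),
            ft_force=self.ft_force.copy(),
            ft_torque=self.ft_torque.copy(),
            kin_t=self.kin_t.copy(),
            kin_pos=self.kin_pos.copy(),
            kin_quat=self.kin_quat.copy(),
            calibration=self.calibration,
            meta=dataclasses.replace(self.meta, extra=dict(self.meta.extra)),
            truth=self.truth,
        )


@dataclass
class ToothFrameRecording:
    """Single-rate (default 100 Hz) streams in the clinical tooth frame.

    All arrays are shaped (3, n) and share one uniform time base:
    forces (N), torques (Nm), displacement from the calibrated origin
    (m), per-axis rotation angles relative to the calibrated
    orientation (deg, rotation-vector components) and rotational
    velocity (deg/s).
    """

    t: np.ndarray  # (n,)
    force: np.ndarray  # (3, n)
    torque: np.ndarray  # (3, n)
    disp: np.ndarray  # (3, n)
    theta: np.ndarray  # (3, n) degrees
    omega: np.ndarray  # (3, n) deg/s
    meta: RecordingMeta
    fs: float = 100.0

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("force", "torque", "disp", "theta", "omega"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (3, n):
                raise ValueError(f"{name} must have shape (3, {n}), got {arr.shape}")
            setattr(self, name, arr)
        if n >= 2:
            steps = np.diff(self.t)
            if np.max(np.abs(steps - steps[0])) > 1e-9:
                raise ValueError("time base is not uniform")

    @property
    def dt(self) -> float:
        return 1.0 / self.fs
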