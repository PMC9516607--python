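"""The 75-feature clinical catalogue and feature extraction.

Every feature is a scalar summary of one tooth-frame trace family —
forces (N), torques (Nm), rotation angles (deg), rotational velocity
(deg/s) or displacement (m) — on one axis and direction, designed to be
clinically interpretable (e.g. "summed extrusion force", "maximum
buccoversion velocity"). The catalogue enumerates:

* forces, 18: AUC (combined + 6 signed), average (combined + 6 signed),
  combined peak, per-axis share of total (3);
* torques, 18: same scheme;
* rotation angles, 18: per-axis share (3), signed maxima (6), signed
  averages (6), per-axis variation (3);
* rotational velocity, 9: signed maxima (6), per-axis variation (3);
* displacement, 12: signed maxima (6), per-axis variation (3),
  per-axis share (3).

``CLINICAL_REFERENCE_SELECTION`` lists the 33-feature subset that
cadaver extraction experiments identified as most informative; it is
kept for comparison against data-driven selections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TOOTH_FRAME, ToothFrameRecording, ToothLabel

AXES = ("X", "Y", "Z")
_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2}
SIGNS = ("+", "-")
_SIGN_SUFFIX = {"+": "pos", "-": "neg"}

FAMILIES = (
    "force_auc", "force_avg", "force_peak", "force_pct",
    "torque_auc", "torque_avg", "torque_peak", "torque_pct",
    "rot_pct", "rot_max", "rot_avg", "rot_var",
    "rotvel_max", "rotvel_var",
    "disp_max", "disp_var", "disp_pct",
)

_TRACE_OF_FAMILY = {
    "force": "force", "torque": "torque", "rot": "theta",
    "rotvel": "omega", "disp": "disp",
}
_ROTATIONAL = {"torque", "rot", "rotvel"}
_UNITS = {
    "force_auc": "Ns", "force_avg": "N", "force_peak": "N", "force_pct": "%",
    "torque_auc": "Nms", "torque_avg": "Nm", "torque_peak": "Nm", "torque_pct": "%",
    "rot_pct": "%", "rot_max": "deg", "rot_avg": "deg", "rot_var": "deg",
    "rotvel_max": "deg/s", "rotvel_var": "deg/s",
    "disp_max": "m", "disp_var": "m", "disp_pct": "%",
}


class FeatureExtractionError(RuntimeError):
    """Raised when a trace yields a non-finite feature value."""


@dataclass(frozen=True)
class FeatureDefinition:
    """One catalogue entry: family + axis + sign, with display metadata."""

    name: str
    family: str
    axis: str  # "X" | "Y" | "Z" | "ALL"
    sign: str  # "+" | "-" | "both"
    units: str
    direction: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown feature family {self.family!r}")
        if self.axis not in AXES + ("ALL",):
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.sign not in SIGNS + ("both",):
            raise ValueError(f"unknown sign {self.sign!r}")


@dataclass(frozen=True)
class FeatureConfig:
    """Definitional conventions left open by the catalogue.

    ``all_norm``: combined-axes ("ALL") magnitude is the Euclidean norm
    of the 3-vector (default) or the sum of absolute components.
    ``average``: signed averages are conditional means over
    sign-matching samples (default) or the signed AUC divided by total
    duration. ``variation``: range max - min (default) or standard
    deviation.
    """

    all_norm: str = "euclidean"
    average: str = "conditional"
    variation: str = "range"

    def __post_init__(self) -> None:
        if self.all_norm not in ("euclidean", "abs_sum"):
            raise ValueError(f"unknown all_norm {self.all_norm!r}")
        if self.average not in ("conditional", "duration"):
            raise ValueError(f"unknown average convention {self.average!r}")
        if self.variation not in ("range", "std"):
            raise ValueError(f"unknown variation convention {self.variation!r}")


def _combined(v: np.ndarray, config: FeatureConfig) -> np.ndarray:
    if config.all_norm == "euclidean":
        return np.linalg.norm(v, axis=0)
    return np.sum(np.abs(v), axis=0)


# ---------------------------------------------------------------------------
# Scalar feature operations
# ---------------------------------------------------------------------------


def auc_signed(s: np.ndarray, dt: float, sign: str) -> float:
    """Trapezoidal integral of the positive (or negative) part of ``s``.

    The negative-direction value is reported positive (integral of
    ``max(-s, 0)``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = np.asarray(s, dtype=float)
    part = np.maximum(s, 0.0) if sign == "+" else np.maximum(-s, 0.0)
    return float(np.trapezoid(part, dx=dt))


def auc_all(v: np.ndarray, dt: float, config: FeatureConfig = FeatureConfig()) -> float:
    """Trapezoidal integral of the combined-axes magnitude."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return float(np.trapezoid(_combined(np.asarray(v, dtype=float), config), dx=dt))


def avg_signed(
    s: np.ndarray, sign: str, dt: float = 1.0, config: FeatureConfig = FeatureConfig()
) -> float:
    """Average of ``s`` in one direction, reported positive.

    Default convention: mean over the sign-matching samples only
    (0 if none match). Alternative ("duration"): signed AUC divided by
    the total recording duration.
    """
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("empty series")
    if config.average == "duration":
        total = dt * (s.size - 1)
        return auc_signed(s, dt, sign) / total if total > 0 else 0.0
    part = s[s > 0] if sign == "+" else -s[s < 0]
    return float(part.mean()) if part.size else 0.0


def avg_all(v: np.ndarray, config: FeatureConfig = FeatureConfig()) -> float:
    """Mean combined-axes magnitude."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] == 0:
        raise ValueError("empty series")
    return float(_combined(v, config).mean())


def peak_all(v: np.ndarray, config: FeatureConfig = FeatureConfig()) -> float:
    """Maximum combined-axes magnitude over time."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] == 0:
        raise ValueError("empty series")
    return float(_combined(v, config).max())


def pct_axis(v: np.ndarray, axis: str, dt: float) -> float:
    """Share (%) of one axis's |AUC| relative to the sum over all axes."""
    v = np.asarray(v, dtype=float)
    aucs = np.trapezoid(np.abs(v), dx=dt, axis=-1)
    total = float(aucs.sum())
    if total == 0.0:
        return 0.0
    return float(100.0 * aucs[_AXIS_INDEX[axis]] / total)


def signed_extreme(s: np.ndarray, sign: str) -> float:
    """Largest excursion of ``s`` in one direction, floored at 0."""
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("empty series")
    return float(max(s.max(), 0.0)) if sign == "+" else float(max(-s.min(), 0.0))


def variation(s: np.ndarray, config: FeatureConfig = FeatureConfig()) -> float:
    """Spread of a trace: range max - min (default) or std."""
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("empty series")
    if config.variation == "std":
        return float(s.std())
    return float(s.max() - s.min())


# ---------------------------------------------------------------------------
# Catalogue
# ---------------------------------------------------------------------------


def _definition(family: str, axis: str, sign: str) -> FeatureDefinition:
    base = family.split("_")[0]
    kind = "rotation" if base in _ROTATIONAL else "translation"
    if axis == "ALL":
        name = f"{family}_all"
        direction = "combined"
    elif sign == "both":
        name = f"{family}_{axis.lower()}"
        direction = (
            f"{TOOTH_FRAME.direction(kind, axis, '+')}"
            f"/{TOOTH_FRAME.direction(kind, axis, '-')}"
        )
    else:
        name = f"{family}_{axis.lower()}_{_SIGN_SUFFIX[sign]}"
        direction = TOOTH_FRAME.direction(kind, axis, sign)
    return FeatureDefinition(
        name=name, family=family, axis=axis, sign=sign,
        units=_UNITS[family], direction=direction,
    )


def build_catalogue() -> list[FeatureDefinition]:
    """The fixed 75-entry feature catalogue, in canonical order."""
    defs: list[FeatureDefinition] = []

    def signed_six(family: str) -> None:
        for axis in AXES:
            for sign in SIGNS:
                defs.append(_definition(family, axis, sign))

    def per_axis(family: str) -> None:
        for axis in AXES:
            defs.append(_definition(family, axis, "both"))

    for base in ("force", "torque"):
        defs.append(_definition(f"{base}_auc", "ALL", "both"))
        signed_six(f"{base}_auc")
        defs.append(_definition(f"{base}_avg", "ALL", "both"))
        signed_six(f"{base}_avg")
        defs.append(_definition(f"{base}_peak", "ALL", "both"))
        per_axis(f"{base}_pct")

    per_axis("rot_pct")
    signed_six("rot_max")
    signed_six("rot_avg")
    per_axis("rot_var")

    signed_six("rotvel_max")
    per_axis("rotvel_var")

    signed_six("disp_max")
    per_axis("disp_var")
    per_axis("disp_pct")

    return defs


#: The 33 features that cadaver extraction experiments found most
#: informative for separating tooth classes; a fixed reference subset.
CLINICAL_REFERENCE_SELECTION: tuple[tuple[str, str, str], ...] = (
    ("force_auc", "ALL", "both"),
    ("force_auc", "X", "+"),
    ("force_auc", "Y", "-"),
    ("force_auc", "Z", "-"),
    ("force_avg", "ALL", "both"),
    ("force_avg", "Y", "+"),
    ("torque_auc", "ALL", "both"),
    ("torque_auc", "Y", "+"),
    ("torque_auc", "Z", "+"),
    ("torque_auc", "Z", "-"),
    ("torque_avg", "ALL", "both"),
    ("torque_avg", "X", "+"),
    ("torque_avg", "Y", "+"),
    ("torque_avg", "Z", "+"),
    ("force_peak", "ALL", "both"),
    ("torque_peak", "ALL", "both"),
    ("force_pct", "Z", "both"),
    ("rot_pct", "Y", "both"),
    ("rot_pct", "Z", "both"),
    ("rot_max", "Y", "+"),
    ("rot_max", "Z", "-"),
    ("rot_avg", "Y", "+"),
    ("rot_avg", "Y", "-"),
    ("rot_avg", "Z", "+"),
    ("rot_avg", "Z", "-"),
    ("rot_var", "Z", "both"),
    ("rotvel_max", "Y", "+"),
    ("rotvel_max", "Y", "-"),
    ("rotvel_max", "Z", "+"),
    ("rotvel_max", "Z", "-"),
    ("rotvel_var", "X", "both"),
    ("rotvel_var", "Y", "both"),
    ("rotvel_var", "Z", "both"),
)


def reference_selection_names() -> list[str]:
    """Catalogue names of the 33-feature clinical reference subset."""
    return [_definition(*spec).name for spec in CLINICAL_REFERENCE_SELECTION]


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------


@dataclass
class FeatureVector:
    """Feature values for one experiment, ordered by catalogue."""

    values: np.ndarray
    names: list[str]
    label: ToothLabel
    experiment_id: str


def _evaluate(
    definition: FeatureDefinition,
    trace: np.ndarray,
    dt: float,
    config: FeatureConfig,
) -> float:
    family = definition.family
    kind = family.split("_")[-1]  # auc | avg | peak | pct | max | var
    if definition.axis == "ALL":
        if kind == "auc":
            return auc_all(trace, dt, config)
        if kind == "avg":
            return avg_all(trace, config)
        if kind == "peak":
            return peak_all(trace, config)
        raise ValueError(f"family {family} has no ALL-axis form")
    s = trace[_AXIS_INDEX[definition.axis]]
    if kind == "auc":
        return auc_signed(s, dt, definition.sign)
    if kind == "avg":
        return avg_signed(s, definition.sign, dt, config)
    if kind == "pct":
        return pct_axis(trace, definition.axis, dt)
    if kind == "max":
        return signed_extreme(s, definition.sign)
    if kind == "var":
        return variation(s, config)
    raise ValueError(f"unhandled feature family {family}")


def extract_features(
    rec: ToothFrameRecording,
    catalogue: list[FeatureDefinition] | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    """Apply every catalogue definition to one preprocessed recording."""
    catalogue = catalogue if catalogue is not None else build_catalogue()
    traces = {
        "force": rec.force,
        "torque": rec.torque,
        "theta": rec.theta,
        "omega": rec.omega,
        "disp": rec.disp,
    }
    values = np.empty(len(catalogue))
    for i, definition in enumerate(catalogue):
        trace = traces[_TRACE_OF_FAMILY[definition.family.split("_")[0]]]
        value = _evaluate(definition, trace, rec.dt, config)
        if not np.isfinite(value):
            raise FeatureExtractionError(
                f"feature {definition.name!r} is non-finite for "
                f"experiment {rec.meta.experiment_id!r}"
            )
        values[i] = value
    return FeatureVector(
        values=values,
        names=[d.name for d in catalogue],
        label=rec.meta.label,
        experiment_id=rec.meta.experiment_id,
    )


def feature_matrix(
    recs: list[ToothFrameRecording],
    catalogue: list[FeatureDefinition] | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Feature table: one row per experiment, catalogue columns plus
    ``experiment_id`` and ``label``."""
    catalogue = catalogue if catalogue is not None else build_catalogue()
    rows = [extract_features(rec, catalogue, config) for rec in recs]
    df = pd.DataFrame(
        [fv.values for fv in rows], columns=[d.name for d in catalogue]
    )
    df.insert(0, "experiment_id", [fv.experiment_id for fv in rows])
    df.insert(1, "label", [fv.label.code for fv in rows])
    return df
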