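"""Readers and writers for recording bundles and pipeline artifacts.

A recording bundle is a directory holding two plain CSV streams and a
JSON sidecar:

* ``ft.csv`` — columns ``t,Fx,Fy,Fz,Tx,Ty,Tz`` (s, N, Nm; ~20 Hz)
* ``kin.csv`` — columns ``t,x,y,z,qw,qx,qy,qz`` (s, m, unit
  quaternion; ~100 Hz)
* ``meta.json`` — experiment id, label code, success flag, calibration
  pose and free-text metadata.

Parsing is header-driven (column order is irrelevant) and validates
monotone timestamps and quaternion norms, reporting the offending row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CalibrationPose,
    RawRecording,
    RecordingMeta,
    ToothFrameRecording,
    ToothLabel,
)

FT_COLUMNS = ["t", "Fx", "Fy", "Fz", "Tx", "Ty", "Tz"]
KIN_COLUMNS = ["t", "x", "y", "z", "qw", "qx", "qy", "qz"]
PROCESSED_COLUMNS = (
    ["t"]
    + ["Fx", "Fy", "Fz", "Tx", "Ty", "Tz"]
    + ["dx", "dy", "dz", "thx", "thy", "thz", "wx", "wy", "wz"]
)


class BundleError(ValueError):
    """Malformed or missing recording bundle."""


def _read_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.is_file():
        raise BundleError(f"missing stream file {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(columns) - set(df.columns)
    if missing:
        raise BundleError(f"{path}: missing columns {sorted(missing)}")
    bad = df[columns].isna().any(axis=1)
    if bad.any():
        raise BundleError(f"{path}: malformed row {int(np.flatnonzero(bad)[0]) + 2}")
    return df[columns]


def write_recording(rec: RawRecording, bundle_dir: str | Path) -> Path:
    """Write one recording as a bundle directory; returns the path."""
    bundle_dir = Path(bundle_dir)
    bundle_dir.mkdir(parents=True, exist_ok=True)
    ft = pd.DataFrame(
        np.column_stack([rec.ft_t, rec.ft_force, rec.ft_torque]), columns=FT_COLUMNS
    )
    kin = pd.DataFrame(
        np.column_stack([rec.kin_t, rec.kin_pos, rec.kin_quat]), columns=KIN_COLUMNS
    )
    # full precision so a write/read round trip is bit-exact
    ft.to_csv(bundle_dir / "ft.csv", index=False, float_format="%.17g")
    kin.to_csv(bundle_dir / "kin.csv", index=False, float_format="%.17g")
    meta = {
        "experiment_id": rec.meta.experiment_id,
        "label": rec.meta.label.code,
        "success": rec.meta.success,
        "calibration": {
            "origin": rec.calibration.origin.tolist(),
            "orientation": rec.calibration.orientation.tolist(),
        },
        "extra": rec.meta.extra,
    }
    (bundle_dir / "meta.json").write_text(json.dumps(meta, indent=2))
    return bundle_dir


def read_recording(bundle_dir: str | Path) -> RawRecording:
    """Read and validate one bundle directory."""
    bundle_dir = Path(bundle_dir)
    meta_path = bundle_dir / "meta.json"
    if not meta_path.is_file():
        raise BundleError(f"missing meta.json in {bundle_dir}")
    meta = json.loads(meta_path.read_text())
    ft = _read_csv(bundle_dir / "ft.csv", FT_COLUMNS)
    kin = _read_csv(bundle_dir / "kin.csv", KIN_COLUMNS)

    for name, t in (("ft.csv", ft["t"].to_numpy()), ("kin.csv", kin["t"].to_numpy())):
        steps = np.diff(t)
        if np.any(steps <= 0):
            row = int(np.flatnonzero(steps <= 0)[0]) + 2  # 1-based + header
            raise BundleError(f"{bundle_dir / name}: non-monotone time at row {row}")
    quat = kin[["qw", "qx", "qy", "qz"]].to_numpy()
    norms = np.linalg.norm(quat, axis=1)
    bad = np.flatnonzero(np.abs(norms - 1.0) > 1e-6)
    if bad.size:
        raise BundleError(
            f"{bundle_dir / 'kin.csv'}: non-unit quaternion at row {int(bad[0]) + 2} "
            f"(norm={norms[bad[0]]:.6g})"
        )

    calibration = CalibrationPose(
        origin=np.asarray(meta["calibration"]["origin"], dtype=float),
        orientation=np.asarray(meta["calibration"]["orientation"], dtype=float),
    )
    return RawRecording(
        ft_t=ft["t"].to_numpy(),
        ft_force=ft[["Fx", "Fy", "Fz"]].to_numpy(),
        ft_torque=ft[["Tx", "Ty", "Tz"]].to_numpy(),
        kin_t=kin["t"].to_numpy(),
        kin_pos=kin[["x", "y", "z"]].to_numpy(),
        kin_quat=quat,
        calibration=calibration,
        meta=RecordingMeta(
            experiment_id=str(meta["experiment_id"]),
            label=ToothLabel.from_code(meta["label"]),
            success=bool(meta.get("success", True)),
            extra=dict(meta.get("extra", {})),
        ),
    )


def list_bundles(root: str | Path) -> list[Path]:
    """Bundle directories under ``root`` (those containing meta.json)."""
    root = Path(root)
    if not root.is_dir():
        return []
    return sorted(p.parent for p in root.glob("*/meta.json"))


def read_dataset(root: str | Path) -> list[RawRecording]:
    bundles = list_bundles(root)
    if not bundles:
        raise BundleError(f"no recordings found under {root}")
    return [read_recording(b) for b in bundles]


def write_dataset(recordings, root: str | Path) -> list[Path]:
    root = Path(root)
    return [
        write_recording(rec, root / rec.meta.experiment_id) for rec in recordings
    ]


# ---------------------------------------------------------------------------
# Processed recordings
# ---------------------------------------------------------------------------


def write_processed(rec: ToothFrameRecording, bundle_dir: str | Path) -> Path:
    bundle_dir = Path(bundle_dir)
    bundle_dir.mkdir(parents=True, exist_ok=True)
    data = np.column_stack(
        [rec.t, rec.force.T, rec.torque.T, rec.disp.T, rec.theta.T, rec.omega.T]
    )
    pd.DataFrame(data, columns=PROCESSED_COLUMNS).to_csv(
        bundle_dir / "processed.csv", index=False, float_format="%.17g"
    )
    meta = {
        "experiment_id": rec.meta.experiment_id,
        "label": rec.meta.label.code,
        "success": rec.meta.success,
        "fs": rec.fs,
        "extra": rec.meta.extra,
    }
    (bundle_dir / "meta.json").write_text(json.dumps(meta, indent=2))
    return bundle_dir


def read_processed(bundle_dir: str | Path) -> ToothFrameRecording:
    bundle_dir = Path(bundle_dir)
    meta = json.loads((bundle_dir / "meta.json").read_text())
    df = _read_csv(bundle_dir / "processed.csv", PROCESSED_COLUMNS)
    return ToothFrameRecording(
        t=df["t"].to_numpy(),
        force=df[["Fx", "Fy", "Fz"]].to_numpy().T,
        torque=df[["Tx", "Ty", "Tz"]].to_numpy().T,
        disp=df[["dx", "dy", "dz"]].to_numpy().T,
        theta=df[["thx", "thy", "thz"]].to_numpy().T,
        omega=df[["wx", "wy", "wz"]].to_numpy().T,
        meta=RecordingMeta(
            experiment_id=str(meta["experiment_id"]),
            label=ToothLabel.from_code(meta["label"]),
            success=bool(meta.get("success", True)),
            extra=dict(meta.get("extra", {})),
        ),
        fs=float(meta.get("fs", 100.0)),
    )


def read_processed_dataset(root: str | Path) -> list[ToothFrameRecording]:
    bundles = list_bundles(root)
    if not bundles:
        raise BundleError(f"no recordings found under {root}")
    return [read_processed(b) for b in bundles]


# ---------------------------------------------------------------------------
# Tabular / JSON artifacts
# ---------------------------------------------------------------------------


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("experiment_id", "label"):
        if col not in df.columns:
            raise BundleError(f"{path}: missing column {col!r}")
    return df


def write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2))


def write_report(report, out_dir: str | Path) -> Path:
    """CVReport -> report.json plus the two confusion-matrix CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_json(report.to_dict(), out_dir / "report.json")
    report.train_confusion.to_csv(out_dir / "confusion_train.csv")
    report.test_confusion.to_csv(out_dir / "confusion_test.csv")
    return out_dir / "report.json"


def catalogue_to_json(catalogue, path: str | Path) -> None:
    write_json(
        {
            "n_features": len(catalogue),
            "features": [
                {
                    "name": d.name,
                    "family": d.family,
                    "axis": d.axis,
                    "sign": d.sign,
                    "units": d.units,
                    "direction": d.direction,
                }
                for d in catalogue
            ],
        },
        path,
    )
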