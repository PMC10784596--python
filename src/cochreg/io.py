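"""File formats: landmark CSV/JSON, centerline CSV/JSON, result and report
JSON, NIfTI masks.

All coordinates are millimetres at full float precision; landmark files
carry 1-based consecutive labels whose order IS the correspondence, so
readers validate it strictly.  JSON output uses a fixed field order so runs
diff cleanly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ParameterError
from .landmarks import LandmarkSet
from .model import Centerline, CochlearParams
from .refinement import CaseReport
from .registration import RegistrationResult
from .synthetic import VoxelMask

__all__ = [
    "write_landmarks_csv",
    "read_landmarks_csv",
    "write_landmarks_json",
    "read_landmarks_json",
    "write_centerline_csv",
    "read_centerline_csv",
    "write_centerline_json",
    "write_result_json",
    "read_result_json",
    "write_report_json",
    "report_table",
    "write_mask_nifti",
]

_LM_COLUMNS = ["label", "x_mm", "y_mm", "z_mm"]


def write_landmarks_csv(lm: LandmarkSet, path: str | Path) -> None:
    df = pd.DataFrame(lm.points, columns=_LM_COLUMNS[1:])
    df.insert(0, "label", lm.labels)
    df.to_csv(path, index=False, float_format="%.17g")


def read_landmarks_csv(path: str | Path, source: str = "model") -> LandmarkSet:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != _LM_COLUMNS:
        raise ParameterError(
            f"landmark CSV must have header {','.join(_LM_COLUMNS)}, got {list(df.columns)}"
        )
    labels = df["label"].to_numpy()
    if not np.array_equal(labels, np.arange(1, len(df) + 1)):
        raise ParameterError("landmark labels must be consecutive from 1 in file order")
    return LandmarkSet(df[_LM_COLUMNS[1:]].to_numpy(float), source=source)


def write_landmarks_json(lm: LandmarkSet, path: str | Path) -> None:
    payload = {
        "units": "mm",
        "source": lm.source,
        "landmarks": [
            {"label": int(l), "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]}
            for l, p in zip(lm.labels, lm.points.tolist())
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_landmarks_json(path: str | Path) -> LandmarkSet:
    payload = json.loads(Path(path).read_text())
    if payload.get("units") != "mm":
        raise ParameterError("landmark JSON must declare units: mm")
    rows = payload["landmarks"]
    labels = [r["label"] for r in rows]
    if labels != list(range(1, len(rows) + 1)):
        raise ParameterError("landmark labels must be consecutive from 1 in file order")
    pts = np.array([[r["x_mm"], r["y_mm"], r["z_mm"]] for r in rows], dtype=float)
    return LandmarkSet(pts, source=payload.get("source", "model"))


def write_centerline_csv(cl: Centerline, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "angle_deg": cl.angles_deg,
            "x_mm": cl.points[:, 0],
            "y_mm": cl.points[:, 1],
            "z_mm": cl.points[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_centerline_csv(path: str | Path) -> Centerline:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["angle_deg", "x_mm", "y_mm", "z_mm"]
    if list(df.columns) != expected:
        raise ParameterError(f"centerline CSV must have header {','.join(expected)}")
    return Centerline(
        df[expected[1:]].to_numpy(float), df["angle_deg"].to_numpy(float)
    )


def write_centerline_json(
    cl: Centerline, path: str | Path, params: CochlearParams | None = None
) -> None:
    params = params or cl.params
    payload = {
        "units": "mm",
        "params": dataclasses.asdict(params) if params is not None else None,
        "samples": [
            {"angle_deg": a, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]}
            for a, p in zip(cl.angles_deg.tolist(), cl.points.tolist())
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def _params_dict(res: RegistrationResult) -> dict:
    p = res.params
    return {
        "alpha": p.alpha, "beta": p.beta, "gamma": p.gamma,
        "t_x": p.t_x, "t_y": p.t_y, "t_z": p.t_z,
        "c_x": p.c_x, "c_y": p.c_y, "c_z": p.c_z,
        "s_xy": p.s_xy, "s_xz": p.s_xz, "s_yz": p.s_yz,
        "reflection": list(p.reflection),
    }


def write_result_json(res: RegistrationResult, path: str | Path) -> None:
    payload = {
        "p_star": _params_dict(res),
        "matrix_row_major": res.matrix.reshape(-1).tolist(),
        "iterations": res.iterations,
        "ssd_history_mm2": list(res.ssd_history),
        "per_landmark_error_mm": {str(k): v for k, v in res.per_landmark_error.items()},
        "mae_mm": res.mae,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_result_json(path: str | Path) -> dict:
    """Raw dict form of a result file (matrix reshaped back to 4×4)."""
    payload = json.loads(Path(path).read_text())
    payload["matrix"] = np.asarray(payload["matrix_row_major"], float).reshape(4, 4)
    return payload


def write_report_json(report: CaseReport, path: str | Path) -> None:
    payload = {
        "steps": [
            {
                "remaining_labels": list(s.remaining),
                "deleted_labels": list(s.deleted),
                "n_landmarks": len(s.remaining),
                "mae_mm": s.mae,
                "iterations": s.iterations,
                "ssd_mm2": s.ssd,
            }
            for s in report.steps
        ],
        "reductions_percent": report.reductions,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def report_table(report: CaseReport) -> str:
    """Human-readable per-step table (description, landmark count, MAE mm)."""
    rows = []
    for i, s in enumerate(report.steps):
        desc = (
            "initial registration"
            if not s.deleted
            else f"deleted landmarks {', '.join(map(str, s.deleted))}"
        )
        rows.append(
            {"step": i, "description": desc, "landmarks": len(s.remaining),
             "MAE (mm)": round(s.mae, 4)}
        )
    return pd.DataFrame(rows).to_string(index=False)


def write_mask_nifti(mask: VoxelMask, path: str | Path) -> None:
    affine = np.diag([mask.spacing_mm] * 3 + [1.0])
    affine[:3, 3] = mask.origin_mm
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms((mask.spacing_mm,) * 3)
    nib.save(img, str(path))
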