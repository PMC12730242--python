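"""File formats: TIFF stacks, delimited trajectory tables, labels, reports.

The native trajectory table is comma-delimited with header
``traj_id,frame,x_px,y_px,x_um,y_um,intensity`` (positions in both pixel and
micrometre units, frames 0-based).  The ``mosaic`` dialect covers the common
particle-tracker export layout — one record per particle per frame with
columns ``trajectory,frame,x,y,intensity`` in pixel units — which is
converted to micrometres at read time via the acquisition geometry.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .qc import QcReport
from .tracking import AcquisitionGeometry
from .trajectory import Trajectory

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "trajectories_to_frame",
    "write_trajectories",
    "read_trajectory_table",
    "write_labels",
    "read_labels",
    "write_json_report",
]

NATIVE_COLUMNS = ["traj_id", "frame", "x_px", "y_px", "x_um", "y_um", "intensity"]
MOSAIC_COLUMNS = ["trajectory", "frame", "x", "y", "intensity"]


def read_image_stack(path: str | Path) -> np.ndarray:
    """Read a single-channel multi-frame TIFF as a (frames, H, W) array."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        if arr.ndim == 4:
            raise ValueError(
                f"expected a single-channel stack, got {arr.shape[-1]} channels"
                if arr.shape[-1] in (3, 4) else
                f"expected a 3D stack, got shape {arr.shape}"
            )
        raise ValueError(f"expected a 3D stack, got shape {arr.shape}")
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        raise ValueError(f"expected a single-channel stack, got {arr.shape[-1]} channels")
    if np.any(np.asarray(arr, dtype=float) < 0):
        raise ValueError("image stack contains negative pixel values")
    return arr


def write_image_stack(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(stack))


def trajectories_to_frame(trajs: Sequence[Trajectory], d: float) -> pd.DataFrame:
    """Flatten trajectories to the native long table (pixels via ``d``)."""
    parts = []
    for t in trajs:
        parts.append(pd.DataFrame({
            "traj_id": t.id,
            "frame": t.frames,
            "x_px": t.x / d,
            "y_px": t.y / d,
            "x_um": t.x,
            "y_um": t.y,
            "intensity": t.intensity,
        }))
    if not parts:
        return pd.DataFrame(columns=NATIVE_COLUMNS)
    return pd.concat(parts, ignore_index=True)[NATIVE_COLUMNS]


def write_trajectories(trajs: Sequence[Trajectory], path: str | Path,
                       d: float) -> None:
    trajectories_to_frame(trajs, d).to_csv(path, index=False)


def _build_trajectories(df: pd.DataFrame, id_col: str, x_um: str, y_um: str,
                        intensity_col: str | None) -> list[Trajectory]:
    out = []
    for tid, grp in df.groupby(id_col, sort=True):
        frames = grp["frame"].to_numpy(dtype=np.int64)
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"trajectory {tid}: frames are not strictly increasing")
        inten = (grp[intensity_col].to_numpy(dtype=float)
                 if intensity_col else None)
        out.append(Trajectory(
            id=int(tid),
            frames=frames,
            x=grp[x_um].to_numpy(dtype=float),
            y=grp[y_um].to_numpy(dtype=float),
            intensity=inten,
        ))
    return out


def read_trajectory_table(path: str | Path, dialect: str = "native",
                          geometry: AcquisitionGeometry | None = None,
                          ) -> list[Trajectory]:
    """Read a trajectory table.

    ``native`` tables carry micrometre positions directly; ``mosaic`` tables
    are in pixels and require ``geometry`` for the conversion.  Detection
    gaps (skipped frames) are preserved.
    """
    df = pd.read_csv(path, comment="#")
    if dialect == "native":
        required = NATIVE_COLUMNS[:1] + ["frame", "x_um", "y_um"]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        inten = "intensity" if "intensity" in df.columns else None
        return _build_trajectories(df, "traj_id", "x_um", "y_um", inten)
    if dialect == "mosaic":
        if geometry is None:
            raise ValueError("mosaic tables are in pixels; geometry is required")
        for col in MOSAIC_COLUMNS[:4]:
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        df = df.assign(x_um=df["x"] * geometry.d, y_um=df["y"] * geometry.d)
        inten = "intensity" if "intensity" in df.columns else None
        return _build_trajectories(df, "trajectory", "x_um", "y_um", inten)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'native' or 'mosaic'")


def write_labels(labels: Sequence[str], traj_ids: Sequence[int],
                 path: str | Path, models: Sequence | None = None) -> None:
    """Ground-truth label sidecar for synthetic datasets."""
    df = pd.DataFrame({"traj_id": list(traj_ids), "label": list(labels)})
    if models is not None:
        df["model"] = [m.kind for m in models]
        df["D"] = [m.D for m in models]
        df["v"] = [m.v for m in models]
    df.to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json_report(obj: dict, path: str | Path) -> None:
    """Deterministic JSON (sorted keys, fixed float repr) for reports."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     allow_nan=True) + "\n")


def qc_report_to_frame(report: QcReport) -> pd.DataFrame:
    rows = [{"traj_id": tid, "status": "accepted", "reason": ""}
            for tid in report.accepted]
    rows += [{"traj_id": tid, "status": "rejected", "reason": reason}
             for tid, reason in report.rejected]
    return pd.DataFrame(rows).sort_values("traj_id").reset_index(drop=True)
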