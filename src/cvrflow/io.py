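"""File I/O: NIfTI volumes, two-column gas-trace CSVs, JSON reports.

Volumes are NIfTI-1 with the TR recorded in the time-axis zoom; traces are
CSV with ``time_s`` and ``mmhg`` columns; ground truth and reports are flat
JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import BoldSeries, MaskVolume, PhysioTrace

__all__ = [
    "save_bold",
    "load_bold",
    "save_masks",
    "load_masks",
    "save_trace",
    "load_trace",
    "save_dataset",
    "save_report",
    "load_report",
]

_MASK_FILES = ("brain", "gm", "wm", "csf", "edema")


def _affine(voxel_dims: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(voxel_dims) + [1.0])


def save_bold(
    bold: BoldSeries,
    path: str | Path,
    voxel_dims: tuple[float, float, float] = (2.3, 2.3, 2.5),
) -> Path:
    """Write a 4D BOLD series as NIfTI-1 with TR in the header."""
    if bold.is_regional:
        raise ValueError("only 4D BOLD series are written as NIfTI")
    img = nib.Nifti1Image(bold.data.astype(np.float32), _affine(voxel_dims))
    img.header.set_zooms(tuple(voxel_dims) + (bold.tr,))
    img.header.set_xyzt_units("mm", "sec")
    path = Path(path)
    nib.save(img, str(path))
    return path


def load_bold(
    path: str | Path, tr_override: float | None = None, slice_axis: int = 2
) -> BoldSeries:
    """Load a 4D NIfTI BOLD series; TR from the header unless overridden."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4D data, got {data.ndim}D")
    tr = tr_override
    if tr is None:
        zooms = img.header.get_zooms()
        # header zooms are float32; round off the representation error
        tr = round(float(zooms[3]), 6) if len(zooms) > 3 else 0.0
        if not tr > 0:
            raise ValueError(f"{path}: no TR in header; pass tr_override")
    return BoldSeries(data=data, tr=float(tr), slice_axis=slice_axis)


def save_masks(masks: MaskVolume, out_dir: str | Path) -> dict[str, Path]:
    """Write each mask label as ``mask_<label>.nii.gz``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for label in _MASK_FILES:
        img = nib.Nifti1Image(
            masks.get(label).astype(np.uint8), _affine(masks.voxel_dims)
        )
        p = out_dir / f"mask_{label}.nii.gz"
        nib.save(img, str(p))
        paths[label] = p
    return paths


def load_masks(mask_dir: str | Path) -> MaskVolume:
    """Load the ``mask_<label>.nii.gz`` set written by :func:`save_masks`."""
    mask_dir = Path(mask_dir)
    arrays = {}
    zooms = (2.3, 2.3, 2.5)
    for label in _MASK_FILES:
        p = mask_dir / f"mask_{label}.nii.gz"
        if not p.exists():
            raise FileNotFoundError(p)
        img = nib.load(str(p))
        arrays[label] = np.asanyarray(img.dataobj) > 0
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MaskVolume(voxel_dims=zooms, **arrays)


def save_trace(trace: PhysioTrace, path: str | Path) -> Path:
    """Write a gas trace as a two-column CSV (time_s, mmhg)."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "mmhg": trace.values}).to_csv(
        path, index=False
    )
    return path


def load_trace(path: str | Path, gas: str = "CO2") -> PhysioTrace:
    """Read a two-column time/value trace (CSV, with or without header)."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if "time_s" in cols:
        t = df[df.columns[cols.index("time_s")]].to_numpy(float)
        v = df[df.columns[cols.index("mmhg")]].to_numpy(float)
    else:
        # headerless two-column file
        df = pd.read_csv(path, header=None)
        t = df[0].to_numpy(float)
        v = df[1].to_numpy(float)
    return PhysioTrace(times=t, values=v, gas=gas)


def save_dataset(dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic dataset (BOLD, masks, traces, truth) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"bold": save_bold(dataset.bold, out_dir / "bold.nii.gz",
                               dataset.masks.voxel_dims)}
    paths.update(save_masks(dataset.masks, out_dir))
    paths["co2"] = save_trace(dataset.co2, out_dir / "co2.csv")
    paths["o2"] = save_trace(dataset.o2, out_dir / "o2.csv")
    truth = dataclasses.asdict(dataset.truth)
    truth["params"] = dataclasses.asdict(dataset.truth.params)
    paths["truth"] = save_report(truth, out_dir / "truth.json")
    return paths


def save_report(report: dict, path: str | Path) -> Path:
    """Write a JSON report deterministically (sorted keys)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path


def load_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
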