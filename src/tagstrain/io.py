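"""Readers and writers for cines, landmark grids, strain curves and reports.

Cines travel as 4-D NIfTI (H x W x 1 x T, in-plane spacing in the header) or
as a DICOM series directory ordered by trigger time.  Landmark grids and
strain curves are plain CSV with 1-based frame/ring/spoke indices and mm
coordinates in the original image plane; boxes, specs and reports are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import BBox, LandmarkGrid, PhantomSpec, StrainCurves, TaggedCine


class CineFormatError(ValueError):
    pass


# ---------------------------------------------------------------- NIfTI cines

def write_cine_nifti(cine: TaggedCine, path) -> None:
    """Write a cine as 4-D NIfTI (H, W, 1, T) plus a JSON sidecar."""
    path = Path(path)
    data = np.transpose(cine.frames, (1, 2, 0))[:, :, None, :]  # H, W, 1, T
    affine = np.diag([cine.pixel_spacing, cine.pixel_spacing, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    dt = 1.0
    if cine.frame_times is not None and len(cine.frame_times) > 1:
        dt = float(cine.frame_times[1] - cine.frame_times[0])
    img.header.set_zooms((cine.pixel_spacing, cine.pixel_spacing, 1.0, dt))
    nib.save(img, path)
    sidecar = {
        "slice_level": cine.slice_level,
        "frame_interval_ms": dt,
        "valid_frames": np.asarray(cine.valid_frames, dtype=bool).tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def _read_nifti_cine(path: Path) -> TaggedCine:
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[2] != 1:
        raise CineFormatError(
            f"{path}: expected a 4-D (H, W, 1, T) cine, got shape {data.shape}")
    zooms = img.header.get_zooms()
    sx, sy = float(zooms[0]), float(zooms[1])
    if sx <= 0 or sy <= 0:
        raise CineFormatError(f"{path}: missing or invalid pixel spacing")
    if abs(sx - sy) > 1e-6:
        raise CineFormatError(f"{path}: anisotropic in-plane spacing unsupported")
    frames = np.transpose(data[:, :, 0, :], (2, 0, 1)).astype(float)
    dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    slice_level, valid = "mid", None
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        slice_level = meta.get("slice_level", slice_level)
        dt = float(meta.get("frame_interval_ms", dt))
        if "valid_frames" in meta:
            valid = np.asarray(meta["valid_frames"], dtype=bool)
    else:
        for lvl in ("basal", "mid", "apical"):
            if lvl in path.stem:
                slice_level = lvl
    times = dt * np.arange(frames.shape[0])
    return TaggedCine(frames, sx, times, slice_level, valid)


def _read_dicom_cine(path: Path) -> TaggedCine:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise CineFormatError(f"{path}: no DICOM files found")
    dsets = [pydicom.dcmread(str(f)) for f in files]
    keys = []
    for ds in dsets:
        if "PixelSpacing" not in ds:
            raise CineFormatError(f"{path}: DICOM series lacks PixelSpacing")
        tt = float(getattr(ds, "TriggerTime", getattr(ds, "InstanceNumber", 0)))
        keys.append(tt)
    order = np.argsort(keys, kind="stable")
    times = np.asarray(keys, dtype=float)[order]
    if np.any(np.diff(times) <= 0):
        raise CineFormatError(f"{path}: non-monotone trigger times in series")
    sp = [float(v) for v in dsets[0].PixelSpacing]
    if abs(sp[0] - sp[1]) > 1e-6:
        raise CineFormatError(f"{path}: anisotropic in-plane spacing unsupported")
    frames = np.stack([dsets[i].pixel_array.astype(float) for i in order])
    level = str(getattr(dsets[0], "SeriesDescription", "")).lower()
    slice_level = next((l for l in ("basal", "mid", "apical") if l in level), "mid")
    return TaggedCine(frames, sp[0], times, slice_level)


def read_cine(path) -> TaggedCine:
    """Read a cine from a 4-D NIfTI file or a DICOM series directory."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_cine(path)
    return _read_nifti_cine(path)


# -------------------------------------------------------------- CSV and JSON

def write_landmarks_csv(grid: LandmarkGrid, path) -> None:
    T, R, S, _ = grid.coords.shape
    t, r, s = np.meshgrid(np.arange(1, T + 1), np.arange(1, R + 1),
                          np.arange(1, S + 1), indexing="ij")
    df = pd.DataFrame({
        "frame": t.ravel(), "ring": r.ravel(), "spoke": s.ravel(),
        "x_mm": grid.coords[..., 0].ravel(), "y_mm": grid.coords[..., 1].ravel(),
    })
    df.to_csv(path, index=False)


def read_landmarks_csv(path) -> LandmarkGrid:
    df = pd.read_csv(path)
    T = int(df["frame"].max())
    R = int(df["ring"].max())
    S = int(df["spoke"].max())
    coords = np.full((T, R, S, 2), np.nan)
    coords[df["frame"] - 1, df["ring"] - 1, df["spoke"] - 1, 0] = df["x_mm"]
    coords[df["frame"] - 1, df["ring"] - 1, df["spoke"] - 1, 1] = df["y_mm"]
    return LandmarkGrid(coords)


def write_strains_csv(curves: StrainCurves, path) -> None:
    pd.DataFrame({
        "frame": np.arange(1, curves.n_frames + 1),
        "eps_R": curves.eps_R,
        "eps_C": curves.eps_C,
        "eps_C_subendo": curves.eps_C_subendo,
        "eps_C_mid": curves.eps_C_mid,
        "eps_C_subepi": curves.eps_C_subepi,
        "eps_C_avg": curves.eps_C_avg,
        "valid": np.asarray(curves.valid, dtype=int),
    }).to_csv(path, index=False)


def read_strains_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_bbox_json(bbox: BBox, path) -> None:
    Path(path).write_text(json.dumps({
        "x_min": bbox.x_min, "y_min": bbox.y_min,
        "x_max": bbox.x_max, "y_max": bbox.y_max,
    }, indent=1))


def read_bbox_json(path) -> BBox:
    d = json.loads(Path(path).read_text())
    return BBox(d["x_min"], d["y_min"], d["x_max"], d["y_max"])


def write_spec_json(spec: PhantomSpec, path) -> None:
    d = dataclasses.asdict(spec)
    d["center"] = [float(c) for c in d["center"]]
    Path(path).write_text(json.dumps(d, indent=1, default=float))


def read_spec_json(path) -> PhantomSpec:
    d = json.loads(Path(path).read_text())
    d["center"] = tuple(d["center"])
    return PhantomSpec(**d)


def write_phantom_case(truth, outdir) -> Path:
    """Write one phantom case (cine + full ground truth) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cine_nifti(truth.cine, outdir / "cine.nii.gz")
    write_landmarks_csv(truth.grid, outdir / "landmarks.csv")
    write_strains_csv(truth.strains, outdir / "strains.csv")
    write_bbox_json(truth.bbox, outdir / "bbox.json")
    write_spec_json(truth.spec, outdir / "spec.json")
    return outdir
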