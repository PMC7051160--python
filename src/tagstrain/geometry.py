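"""Landmark-grid construction and image-space preprocessing.

Builds the 7-ring x 24-spoke anatomic landmark grid from end-diastolic
contours, computes the myocardial bounding box with its safety enlargement,
and performs the fixed-size spatial padding, temporal normalization and
ROI crop/resample with exact, invertible coordinate transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import LineString, Point, Polygon

from .types import (
    BBox,
    ContourPair,
    LandmarkGrid,
    N_FRAMES,
    N_RINGS,
    N_SPOKES,
    PAD_SIZE,
    CROP_SIZE,
    TaggedCine,
)


class MalformedContourError(ValueError):
    pass


def septal_midpoint(contours: ContourPair) -> float:
    """Angle (radians, about the myocardial centroid) of the septal midpoint.

    The septal midpoint lies halfway between the anterior and posterior RV
    insertion points along the shorter arc; the angular mean is computed on
    the circle so wrap-around at 0/360 degrees is handled.
    """
    c = np.asarray(Polygon(contours.epi).centroid.coords[0])
    ants = contours.rv_insertion_anterior - c
    post = contours.rv_insertion_posterior - c
    na, np_ = np.linalg.norm(ants), np.linalg.norm(post)
    if na == 0 or np_ == 0 or np.allclose(ants, post):
        raise ValueError("degenerate RV insertion points")
    v = ants / na + post / np_
    if np.linalg.norm(v) < 1e-12:
        raise ValueError("RV insertion points are antipodal; septal side undefined")
    return float(np.mod(np.arctan2(v[1], v[0]), 2 * np.pi))


def _ray_hit(poly: Polygon, origin: np.ndarray, direction: np.ndarray,
             length: float) -> np.ndarray:
    """First intersection of a ray with a polygon boundary, nearest the origin."""
    ray = LineString([origin, origin + direction * length])
    hit = ray.intersection(poly.exterior)
    if hit.is_empty:
        raise MalformedContourError("spoke fails to intersect contour")
    pts = []
    if hit.geom_type == "Point":
        pts = [hit]
    else:
        pts = [g for g in getattr(hit, "geoms", []) if g.geom_type == "Point"]
        if not pts:  # e.g. a grazing LineString
            raise MalformedContourError("degenerate spoke/contour intersection")
    best = min(pts, key=lambda p: Point(origin).distance(p))
    return np.asarray(best.coords[0])


def build_landmark_grid(contours: ContourPair, *, direction: str = "ccw") -> LandmarkGrid:
    """Place the 168 landmarks (7 transmural rings x 24 spokes) at end diastole.

    Spokes are straight rays from the myocardial centroid at equal angular
    increments starting at the septal midpoint (counterclockwise in (x, y) by
    default).  Along each spoke, landmarks sit strictly inside the wall at
    transmural fractions r/8 (r = 1..7) between the endocardial and
    epicardial intersections.
    """
    if direction not in ("ccw", "cw"):
        raise ValueError("direction must be 'ccw' or 'cw'")
    endo_poly = Polygon(contours.endo)
    epi_poly = Polygon(contours.epi)
    if not endo_poly.is_valid or not epi_poly.is_valid:
        raise MalformedContourError("contours must be simple polygons")
    if not epi_poly.contains(endo_poly):
        raise MalformedContourError("endocardial contour must lie inside epicardial")

    center = np.asarray(epi_poly.centroid.coords[0])
    theta0 = septal_midpoint(contours)
    sign = 1.0 if direction == "ccw" else -1.0
    minx, miny, maxx, maxy = epi_poly.bounds
    reach = 3.0 * max(maxx - minx, maxy - miny)

    coords = np.empty((1, N_RINGS, N_SPOKES, 2))
    fracs = (np.arange(1, N_RINGS + 1) / (N_RINGS + 1))[:, None]  # r/8
    for k in range(N_SPOKES):
        th = theta0 + sign * 2 * np.pi * k / N_SPOKES
        d = np.array([np.cos(th), np.sin(th)])
        e_pt = _ray_hit(endo_poly, center, d, reach)
        p_pt = _ray_hit(epi_poly, center, d, reach)
        coords[0, :, k, :] = e_pt[None, :] + fracs * (p_pt - e_pt)[None, :]
    return LandmarkGrid(coords)


def compute_bbox(myocardium, enlargement: float = 0.6, *,
                 pixel_spacing: float = 1.0, image_shape=None) -> BBox:
    """Axis-aligned myocardial extent enlarged by ``enlargement`` per dimension.

    ``myocardium`` is either a ContourPair (epicardial extent, mm -> pixels via
    ``pixel_spacing``) or a boolean mask.  Each dimension is scaled by
    (1 + enlargement) about the box center, then clipped to the image.
    """
    if enlargement < 0:
        raise ValueError("enlargement must be >= 0")
    if isinstance(myocardium, ContourPair):
        pts = myocardium.epi / pixel_spacing
        x0, y0 = pts.min(axis=0)
        x1, y1 = pts.max(axis=0)
    else:
        mask = np.asarray(myocardium, dtype=bool)
        if not mask.any():
            raise ValueError("empty myocardial extent")
        rows, cols = np.nonzero(mask)
        x0, x1 = float(cols.min()), float(cols.max() + 1)
        y0, y1 = float(rows.min()), float(rows.max() + 1)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("empty myocardial extent")
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    hw = (x1 - x0) / 2 * (1 + enlargement)
    hh = (y1 - y0) / 2 * (1 + enlargement)
    box = BBox(cx - hw, cy - hh, cx + hw, cy + hh)
    if image_shape is not None:
        box = box.clipped(width=image_shape[1], height=image_shape[0])
    return box


def pad_and_fix_frames(cine: TaggedCine, *, size: int = PAD_SIZE,
                       n_frames: int = N_FRAMES):
    """Zero-pad frames to ``size`` x ``size`` and fix the cine to ``n_frames``.

    Spatial padding is symmetric with the extra pixel on the trailing side when
    the deficit is odd.  Cines shorter than ``n_frames`` are padded with
    all-zero frames at the end (marked invalid in the returned mask); longer
    cines keep their first ``n_frames`` frames.

    Returns (padded cine, (row_offset, col_offset)) where the offsets give the
    position of the original pixel (0, 0) inside the padded frame.
    """
    T, H, W = cine.frames.shape
    if H > size or W > size:
        raise ValueError(f"input frame {H}x{W} exceeds the {size} protocol matrix")
    py, px = (size - H) // 2, (size - W) // 2
    frames = np.zeros((min(T, n_frames) if T > n_frames else T, size, size),
                      dtype=cine.frames.dtype)
    src = cine.frames[:n_frames]
    frames[:, py:py + H, px:px + W] = src
    valid = np.asarray(cine.valid_frames)[:n_frames].copy()
    if frames.shape[0] < n_frames:
        deficit = n_frames - frames.shape[0]
        frames = np.concatenate(
            [frames, np.zeros((deficit, size, size), dtype=frames.dtype)], axis=0)
        valid = np.concatenate([valid, np.zeros(deficit, dtype=bool)])
    times = cine.frame_times
    if times is not None:
        dt = times[1] - times[0] if len(times) > 1 else 1.0
        times = times[0] + dt * np.arange(n_frames)
    out = TaggedCine(frames, cine.pixel_spacing, times, cine.slice_level, valid)
    return out, (py, px)


@dataclass
class CropTransform:
    """Invertible affine map between cropped-pixel and original coordinates.

    A cropped pixel center ``u`` (0-based) maps to the original pixel
    coordinate ``x0 + (u + 0.5) * scale - 0.5``; mm = pixel * pixel_spacing.
    """

    x0: float
    y0: float
    sx: float
    sy: float
    pixel_spacing: float

    def cropped_to_orig_px(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        out = np.empty_like(pts)
        out[..., 0] = self.x0 + (pts[..., 0] + 0.5) * self.sx - 0.5
        out[..., 1] = self.y0 + (pts[..., 1] + 0.5) * self.sy - 0.5
        return out

    def orig_px_to_cropped(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        out = np.empty_like(pts)
        out[..., 0] = (pts[..., 0] + 0.5 - self.x0) / self.sx - 0.5
        out[..., 1] = (pts[..., 1] + 0.5 - self.y0) / self.sy - 0.5
        return out

    def cropped_to_mm(self, pts: np.ndarray) -> np.ndarray:
        return self.cropped_to_orig_px(pts) * self.pixel_spacing

    def mm_to_cropped(self, pts: np.ndarray) -> np.ndarray:
        return self.orig_px_to_cropped(np.asarray(pts, dtype=float) / self.pixel_spacing)


def crop_resample(cine: TaggedCine, box: BBox, *, size: int = CROP_SIZE):
    """Crop every frame to ``box`` and resample to ``size`` x ``size`` (bicubic).

    The same (end-diastolic) box is applied to every frame.  Returns the
    cropped cine together with the CropTransform relating cropped pixels to
    original image coordinates.
    """
    T, H, W = cine.frames.shape
    if box.width <= 0 or box.height <= 0:
        raise ValueError("degenerate bounding box")
    if box.x_min < 0 or box.y_min < 0 or box.x_max > W or box.y_max > H:
        raise ValueError("bounding box exceeds image bounds")
    tf = CropTransform(box.x_min, box.y_min, box.width / size, box.height / size,
                       cine.pixel_spacing)
    u = np.arange(size)
    xs = tf.x0 + (u + 0.5) * tf.sx - 0.5
    ys = tf.y0 + (u + 0.5) * tf.sy - 0.5
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    out = np.empty((T, size, size), dtype=float)
    for t in range(T):
        out[t] = map_coordinates(cine.frames[t].astype(float), [yy, xx],
                                 order=3, mode="nearest")
    cropped = TaggedCine(out, cine.pixel_spacing, cine.frame_times,
                         cine.slice_level, np.asarray(cine.valid_frames).copy())
    return cropped, tf


def normalize_intensity(frames: np.ndarray) -> np.ndarray:
    """Per-frame min-max normalization to [0, 1] (constant frames map to 0)."""
    frames = np.asarray(frames, dtype=float)
    lo = frames.min(axis=(-2, -1), keepdims=True)
    hi = frames.max(axis=(-2, -1), keepdims=True)
    rng = np.where(hi > lo, hi - lo, 1.0)
    return (frames - lo) / rng
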