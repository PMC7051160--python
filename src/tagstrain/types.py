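"""Domain containers shared across the pipeline.

Conventions
-----------
* Pixel coordinates are 0-based with ``x`` = column, ``y`` = row and pixel
  centers at integer positions.  Physical position (mm) = pixel * pixel_spacing.
* Bounding boxes are half-open: ``[x_min, x_max) x [y_min, y_max)``.
* Frame, ring and spoke indices in public APIs are 1-based (frame 1 is the
  end-diastolic reference); array storage is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

N_RINGS = 7
N_SPOKES = 24
N_LANDMARKS = N_RINGS * N_SPOKES  # 168
N_FRAMES = 20
PAD_SIZE = 256
CROP_SIZE = 128

# ring indices (1-based) used for layer-wise circumferential strain
RING_SUBENDO = 2
RING_MIDWALL = 4
RING_SUBEPI = 6


@dataclass
class TaggedCine:
    """One slice's frame stack with spacing/timing metadata.

    frames : (T, H, W) float array of intensities.
    valid_frames : boolean (T,) mask; False marks frames appended purely to
        reach the fixed temporal length.
    """

    frames: np.ndarray
    pixel_spacing: float
    frame_times: Optional[np.ndarray] = None
    slice_level: str = "mid"
    valid_frames: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("cine intensities must be finite")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.valid_frames is None:
            self.valid_frames = np.ones(self.frames.shape[0], dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape


@dataclass
class ContourPair:
    """Endo/epicardial contours (mm, image plane) plus RV insertion points."""

    endo: np.ndarray
    epi: np.ndarray
    rv_insertion_anterior: np.ndarray
    rv_insertion_posterior: np.ndarray

    def __post_init__(self) -> None:
        self.endo = np.asarray(self.endo, dtype=float)
        self.epi = np.asarray(self.epi, dtype=float)
        self.rv_insertion_anterior = np.asarray(self.rv_insertion_anterior, dtype=float)
        self.rv_insertion_posterior = np.asarray(self.rv_insertion_posterior, dtype=float)
        for name, c in (("endo", self.endo), ("epi", self.epi)):
            if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
                raise ValueError(f"{name} contour must be an (N, 2) point list, N >= 3")


@dataclass
class LandmarkGrid:
    """Per-frame 7-ring x 24-spoke landmark coordinates in mm.

    coords : (T, 7, 24, 2) array, last axis (x, y).  Frame 1 (index 0) is the
    end-diastolic reference configuration.
    """

    coords: np.ndarray
    reference_frame: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[1:] != (N_RINGS, N_SPOKES, 2):
            raise ValueError("coords must have shape (T, 7, 24, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, t: int) -> np.ndarray:
        """Landmarks of 1-based frame ``t`` as a (7, 24, 2) array."""
        if not 1 <= t <= self.n_frames:
            raise ValueError(f"frame {t} out of range 1..{self.n_frames}")
        return self.coords[t - 1]


@dataclass
class BBox:
    """Axis-aligned box, 0-based pixel coordinates, half-open."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("box must satisfy x_min < x_max and y_min < y_max")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def corners(self) -> np.ndarray:
        """(x_min, y_min, x_max, y_max) as an array (two-corner encoding)."""
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max], float)

    def clipped(self, width: int, height: int) -> "BBox":
        return BBox(
            max(self.x_min, 0.0),
            max(self.y_min, 0.0),
            min(self.x_max, float(width)),
            min(self.y_max, float(height)),
        )

    @staticmethod
    def from_corners(c) -> "BBox":
        c = np.asarray(c, dtype=float).ravel()
        return BBox(c[0], c[1], c[2], c[3])


@dataclass
class StrainCurves:
    """Per-frame slice strains with 1-based end-systolic frame index.

    eps_C is the whole-slice circumferential strain reported from the midwall
    ring; eps_C_avg additionally averages all seven rings.
    """

    eps_R: np.ndarray
    eps_C: np.ndarray
    eps_C_subendo: np.ndarray
    eps_C_mid: np.ndarray
    eps_C_subepi: np.ndarray
    eps_C_avg: np.ndarray
    es_frame: int
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        T = len(self.eps_R)
        if self.valid is None:
            self.valid = np.ones(T, dtype=bool)
        for a in (self.eps_C, self.eps_C_subendo, self.eps_C_mid,
                  self.eps_C_subepi, self.eps_C_avg, self.valid):
            if len(a) != T:
                raise ValueError("all strain arrays must share the frame axis")

    @property
    def n_frames(self) -> int:
        return len(self.eps_R)


@dataclass
class PhantomSpec:
    """Analytic deformation + imaging parameters of a synthetic tagged cine.

    Defaults follow a short-axis tagging protocol: 1.4 mm in-plane pixels,
    6 mm tag grid period, 20 reconstructed frames at 41 ms, 256 matrix.
    Geometry defaults describe a mid-ventricular annulus (endo 25 mm /
    epi 40 mm at end diastole) contracting by 30% of the endocardial radius
    at end systole, which yields a midwall circumferential strain near -0.15.
    """

    R_endo: float = 25.0
    R_epi: float = 40.0
    center: Optional[tuple] = None  # mm; default = image center
    contraction: float = 0.30
    twist_deg: float = 5.0
    es_frame: int = 9
    n_frames: int = N_FRAMES
    tag_spacing: float = 6.0
    fade_tau: float = 20.0
    noise_sd: float = 0.03
    pixel_spacing: float = 1.4
    image_size: int = PAD_SIZE
    septal_angle_deg: float = 200.0
    slice_level: str = "mid"
    seed: int = 0
    diastolic_recovery: float = 0.3  # residual contraction fraction at last frame
    twist_transmural: float = 0.0   # extra rotation (deg) of the epicardial ring vs endo
    frame_interval_ms: float = 41.0
    tag_contrast: float = 0.8
    noise_model: str = "gaussian"   # or "rician"

    def __post_init__(self) -> None:
        if not 0 < self.R_endo < self.R_epi:
            raise ValueError("require 0 < R_endo < R_epi")
        if not 0 <= self.contraction < 1:
            raise ValueError("contraction must lie in [0, 1)")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if not 1 <= self.es_frame <= self.n_frames:
            raise ValueError("es_frame must lie within 1..n_frames")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if self.center is None:
            c = (self.image_size - 1) / 2.0 * self.pixel_spacing
            self.center = (c, c)

    def with_(self, **kw) -> "PhantomSpec":
        return replace(self, **kw)


@dataclass
class PhantomTruth:
    """A rendered phantom cine bundled with its exact ground truth."""

    cine: TaggedCine
    grid: LandmarkGrid
    contours: ContourPair
    bbox: BBox
    strains: StrainCurves
    spec: PhantomSpec


@dataclass
class TrainConfig:
    """Optimization settings for the localization / tracking networks.

    ``schedule`` is (decay_factor, period_epochs, start_epoch): after
    ``start_epoch`` the learning rate is multiplied by ``decay_factor`` every
    ``period_epochs`` epochs.  ``omega`` weights the strain-error terms of the
    tracker's composite loss relative to the position term.
    """

    learning_rate: float = 1e-3
    schedule: tuple = (2 ** -0.5, 5, 10)
    batch_size: int = 16
    epochs: int = 30
    omega: float = 5.0
    seed: int = 0
    arch: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate for 1-based ``epoch`` under the step-decay schedule."""
        factor, period, start = self.schedule
        n = max(0, (epoch - start - 1) // period + 1) if epoch > start else 0
        return self.learning_rate * factor ** n


@dataclass
class EvalReport:
    """Agreement summary: bias/precision/limits of agreement + RMS errors."""

    bias: float
    precision: float
    loa_low: float
    loa_high: float
    rms_ed: Optional[float] = None
    rms_es: Optional[float] = None
    n: int = 0
    p_values: dict = field(default_factory=dict)
    alpha_adjusted: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "bias": self.bias,
            "precision": self.precision,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "rms_ed": self.rms_ed,
            "rms_es": self.rms_es,
            "n": self.n,
            "p_values": self.p_values,
            "alpha_adjusted": self.alpha_adjusted,
        }
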