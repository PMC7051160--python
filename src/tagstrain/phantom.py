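"""Synthetic short-axis tagged cine phantom with analytic ground truth.

The myocardium is an incompressible annulus: a material point at ED polar
radius R moves to r(R, t) = sqrt(R^2 - a(t)) with a(t) = R_endo^2 -
r_endo(t)^2, which preserves the in-plane area between any two material rings
exactly.  A rigid rotation (peak ``twist_deg``) is superimposed.  Because the
map is radial, circumferential Green strain of a material ring has the closed
form ((r/R)^2 - 1)/2 and radial strain between two material rings is
((delta_r / delta_R)^2 - 1)/2, so every rendered cine carries exact landmark
trajectories and strain curves.

The tag pattern is grid SPAMM: a product of two squared-sinusoid stripe
patterns laid down in the reference (ED) configuration and advected by the
deformation, with exponential contrast decay emulating tag fading.  The blood
pool is rendered bright and tag-free from frame 2 onward (washout); the
background is dark and tag-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import build_landmark_grid, compute_bbox
from .strain import slice_strain_curves
from .types import (
    BBox,
    ContourPair,
    LandmarkGrid,
    N_RINGS,
    PhantomSpec,
    PhantomTruth,
    RING_MIDWALL,
    RING_SUBENDO,
    RING_SUBEPI,
    StrainCurves,
    TaggedCine,
)

_TISSUE = 0.7
_BLOOD = 0.95
_BACKGROUND = 0.05


def contraction_profile(spec: PhantomSpec, t) -> np.ndarray:
    """Normalized contraction w(t) in [0, 1]: raised cosine up to the
    end-systolic frame, partial raised-cosine recovery afterwards down to
    ``diastolic_recovery`` at the final frame.  ``t`` is 1-based."""
    t = np.asarray(t, dtype=float)
    es, T = spec.es_frame, spec.n_frames
    up = 0.5 * (1 - np.cos(np.pi * (t - 1) / max(es - 1, 1)))
    wr = spec.diastolic_recovery
    down = wr + (1 - wr) * 0.5 * (1 + np.cos(np.pi * (t - es) / max(T - es, 1)))
    return np.where(t <= es, np.where(t < 1, 0.0, up), down)


@dataclass
class AnnulusDeformation:
    """Point transform of one frame: reference (ED) mm -> deformed mm."""

    center: np.ndarray
    a: float           # mm^2, squared-radius offset
    twist: float       # radians, rigid component
    twist_grad: float  # radians per unit transmural coordinate (R - R_endo)/(R_epi - R_endo)
    R_endo: float
    R_epi: float

    def _rot(self, R):
        if self.twist_grad == 0.0:
            return self.twist
        frac = np.clip((R - self.R_endo) / (self.R_epi - self.R_endo), 0.0, 1.0)
        return self.twist + self.twist_grad * frac

    def forward(self, pts: np.ndarray) -> np.ndarray:
        """Map reference positions (..., 2) mm to their deformed positions."""
        pts = np.asarray(pts, dtype=float)
        rel = pts - self.center
        R = np.linalg.norm(rel, axis=-1)
        r2 = R**2 - self.a
        if np.any(r2 <= 0):
            raise ValueError("deformation collapses a material radius; invalid spec")
        theta = np.arctan2(rel[..., 1], rel[..., 0]) + self._rot(R)
        r = np.sqrt(r2)
        return self.center + np.stack([r * np.cos(theta), r * np.sin(theta)], axis=-1)

    def inverse_polar(self, r: np.ndarray, theta: np.ndarray):
        """Deformed polar (r, theta) about the center -> reference polar."""
        R = np.sqrt(r**2 + self.a)
        return R, theta - self._rot(R)


def deformation_map(spec: PhantomSpec, t: int) -> AnnulusDeformation:
    """Deformation of 1-based frame ``t`` (frame 1 is the identity)."""
    if not 1 <= t <= spec.n_frames:
        raise ValueError(f"frame {t} out of range 1..{spec.n_frames}")
    w = float(contraction_profile(spec, t))
    r_endo = spec.R_endo * (1 - spec.contraction * w)
    a = spec.R_endo**2 - r_endo**2
    return AnnulusDeformation(
        center=np.asarray(spec.center, dtype=float),
        a=a,
        twist=np.deg2rad(spec.twist_deg) * w,
        twist_grad=np.deg2rad(spec.twist_transmural) * w,
        R_endo=spec.R_endo,
        R_epi=spec.R_epi,
    )


def _ring_radii(spec: PhantomSpec) -> np.ndarray:
    """ED radii of the 7 landmark rings (transmural fractions 1/8..7/8)."""
    fr = np.arange(1, N_RINGS + 1) / (N_RINGS + 1)
    return spec.R_endo + fr * (spec.R_epi - spec.R_endo)


def analytic_strain(spec: PhantomSpec, t: int) -> dict:
    """Closed-form slice strains at 1-based frame ``t``.

    Circumferential Green strain of the material ring at ED radius R is
    ((r(R,t)/R)^2 - 1)/2 = -a(t) / (2 R^2); radial strain uses the separation
    between the innermost and outermost landmark rings.
    """
    d = deformation_map(spec, t)
    Rr = _ring_radii(spec)
    if np.any(Rr**2 <= d.a):
        raise ValueError("deformation collapses a landmark ring; invalid spec")
    r = np.sqrt(Rr**2 - d.a)
    eps_C_rings = -d.a / (2 * Rr**2)
    dr, dR = r[-1] - r[0], Rr[-1] - Rr[0]
    return {
        "eps_R": ((dr / dR) ** 2 - 1) / 2,
        "eps_C_rings": eps_C_rings,
        "eps_C_subendo": eps_C_rings[RING_SUBENDO - 1],
        "eps_C_mid": eps_C_rings[RING_MIDWALL - 1],
        "eps_C_subepi": eps_C_rings[RING_SUBEPI - 1],
        "eps_C_avg": eps_C_rings.mean(),
    }


def analytic_strain_curves(spec: PhantomSpec) -> StrainCurves:
    rows = [analytic_strain(spec, t) for t in range(1, spec.n_frames + 1)]
    curves = StrainCurves(
        eps_R=np.array([r["eps_R"] for r in rows]),
        eps_C=np.array([r["eps_C_mid"] for r in rows]),
        eps_C_subendo=np.array([r["eps_C_subendo"] for r in rows]),
        eps_C_mid=np.array([r["eps_C_mid"] for r in rows]),
        eps_C_subepi=np.array([r["eps_C_subepi"] for r in rows]),
        eps_C_avg=np.array([r["eps_C_avg"] for r in rows]),
        es_frame=1,
    )
    curves.es_frame = int(np.argmin(curves.eps_C_mid)) + 1
    return curves


def make_contours(spec: PhantomSpec, n_points: int = 240) -> ContourPair:
    """Circular ED contours with RV insertion points 45 deg either side of the
    septal direction on the epicardium.

    Sampling is phased at the septal angle so that every landmark spoke passes
    exactly through a contour vertex; the contour-built grid then coincides
    with the analytic ring layout to numerical precision.
    """
    sa = np.deg2rad(spec.septal_angle_deg)
    th = sa + np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    c = np.asarray(spec.center, dtype=float)
    endo = c + spec.R_endo * np.stack([np.cos(th), np.sin(th)], axis=1)
    epi = c + spec.R_epi * np.stack([np.cos(th), np.sin(th)], axis=1)
    ins = []
    for off in (+np.pi / 4, -np.pi / 4):
        ins.append(c + spec.R_epi * np.array([np.cos(sa + off), np.sin(sa + off)]))
    return ContourPair(endo, epi, ins[0], ins[1])


def ed_grid(spec: PhantomSpec) -> LandmarkGrid:
    """Analytic ED landmark grid: 7 concentric rings x 24 equally spaced
    spokes starting at the septal direction (counterclockwise)."""
    sa = np.deg2rad(spec.septal_angle_deg)
    th = sa + 2 * np.pi * np.arange(24) / 24
    unit = np.stack([np.cos(th), np.sin(th)], axis=-1)          # (24, 2)
    coords = np.asarray(spec.center) + _ring_radii(spec)[:, None, None] * unit
    return LandmarkGrid(coords[None, ...])


def ground_truth_grid(spec: PhantomSpec) -> LandmarkGrid:
    """Exact landmark trajectories: the ED grid advected by the annulus map."""
    ed = ed_grid(spec).coords[0]
    coords = np.empty((spec.n_frames, *ed.shape))
    for t in range(1, spec.n_frames + 1):
        coords[t - 1] = deformation_map(spec, t).forward(ed)
    return LandmarkGrid(coords)


def render_cine(spec: PhantomSpec) -> PhantomTruth:
    """Render a tagged cine and attach grid, contours, bbox and strain truth."""
    size, sp = spec.image_size, spec.pixel_spacing
    margin = spec.R_epi * 1.6  # enlarged-box half-extent must fit in the image
    cx, cy = spec.center
    if (cx - margin < -0.5 * sp or cy - margin < -0.5 * sp
            or cx + margin > (size - 0.5) * sp or cy + margin > (size - 0.5) * sp):
        raise ValueError("image_size too small for the epicardium + bbox margin")

    idx = np.arange(size) * sp
    xg, yg = np.meshgrid(idx, idx)  # (row, col) -> (y, x) mm
    relx, rely = xg - cx, yg - cy
    rpix = np.hypot(relx, rely)
    theta = np.arctan2(rely, relx)

    rng = np.random.default_rng(spec.seed)
    frames = np.empty((spec.n_frames, size, size), dtype=np.float32)
    s = spec.tag_spacing
    for t in range(1, spec.n_frames + 1):
        d = deformation_map(spec, t)
        r_endo_t = np.sqrt(max(spec.R_endo**2 - d.a, 0.0))
        r_epi_t = np.sqrt(spec.R_epi**2 - d.a)
        myo = (rpix >= r_endo_t) & (rpix <= r_epi_t)
        blood = rpix < r_endo_t

        if np.isfinite(spec.fade_tau):
            fade = spec.tag_contrast * np.exp(-(t - 1) / spec.fade_tau)
        else:
            fade = spec.tag_contrast
        R, Theta = d.inverse_polar(rpix, theta)
        X1, X2 = R * np.cos(Theta), R * np.sin(Theta)
        tags = (1 - fade * np.cos(np.pi * X1 / s) ** 2) * \
               (1 - fade * np.cos(np.pi * X2 / s) ** 2)

        img = np.full((size, size), _BACKGROUND)
        img[myo] = _TISSUE * tags[myo]
        if t == 1:
            img[blood] = _BLOOD * tags[blood]
        else:
            img[blood] = _BLOOD
        if spec.noise_sd > 0:
            if spec.noise_model == "rician":
                n1 = rng.normal(0.0, spec.noise_sd, img.shape)
                n2 = rng.normal(0.0, spec.noise_sd, img.shape)
                img = np.hypot(img + n1, n2)
            else:
                img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        frames[t - 1] = img

    contours = make_contours(spec)
    grid = ground_truth_grid(spec)
    bbox = compute_bbox(contours, 0.6, pixel_spacing=sp, image_shape=(size, size))
    cine = TaggedCine(
        frames, sp, spec.frame_interval_ms * np.arange(spec.n_frames),
        spec.slice_level)
    return PhantomTruth(cine, grid, contours, bbox,
                        analytic_strain_curves(spec), spec)


@dataclass
class JitterRanges:
    """Half-widths of the uniform per-case perturbations used by make_dataset.

    Defaults describe a plausible population spread around the base spec:
    geometry a few mm, contraction +/-0.10 (midwall circumferential strain
    spread ~0.02-0.03), twist a few degrees, ES timing one frame.  The septal
    direction is deliberately not jittered: the phantom renders no right
    ventricle, so nothing in the image pins the angular origin.
    """

    R_endo: float = 3.0          # mm
    wall_thickness: float = 2.0  # mm
    center: float = 10.0         # mm
    contraction: float = 0.10
    twist_deg: float = 3.0
    es_frame: int = 1
    noise_sd: float = 0.01
    septal_angle_deg: float = 0.0


def sample_spec(base: PhantomSpec, jit: JitterRanges, rng: np.random.Generator,
                seed: int) -> PhantomSpec:
    u = lambda h: rng.uniform(-h, h)
    R_endo = base.R_endo + u(jit.R_endo)
    wall = (base.R_epi - base.R_endo) + u(jit.wall_thickness)
    c0 = np.asarray(base.center, dtype=float)
    return base.with_(
        R_endo=R_endo,
        R_epi=R_endo + max(wall, 4.0),
        center=tuple(c0 + np.array([u(jit.center), u(jit.center)])),
        contraction=float(np.clip(base.contraction + u(jit.contraction), 0.0, 0.49)),
        twist_deg=base.twist_deg + u(jit.twist_deg),
        es_frame=int(np.clip(base.es_frame + rng.integers(-jit.es_frame,
                                                          jit.es_frame + 1),
                             2, base.n_frames - 1)),
        noise_sd=max(base.noise_sd + u(jit.noise_sd), 0.0),
        septal_angle_deg=base.septal_angle_deg + u(jit.septal_angle_deg),
        seed=seed,
    )


def split_indices(n: int, rng: np.random.Generator) -> dict:
    """Deterministic 72/18/10 train/val/test split (90/10, then 80/20)."""
    order = rng.permutation(n)
    n_test = int(round(n * 0.10))
    n_val = int(round((n - n_test) * 0.20))
    return {
        "test": sorted(order[:n_test].tolist()),
        "val": sorted(order[n_test:n_test + n_val].tolist()),
        "train": sorted(order[n_test + n_val:].tolist()),
    }


def make_dataset(n: int, base_spec: PhantomSpec | None = None,
                 jitter: JitterRanges | None = None, seed: int = 0):
    """Generate ``n`` phantom cases plus a train/val/test split.

    Returns (cases, split) with ``cases`` a list of PhantomTruth and ``split``
    a dict of index lists.  Fully determined by ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec or PhantomSpec()
    jit = jitter or JitterRanges()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    case_seeds = [int(s) for s in
                  np.random.default_rng(ss.spawn(1)[0]).integers(0, 2**31 - 1, n)]
    cases = [render_cine(sample_spec(base, jit, rng, case_seeds[i]))
             for i in range(n)]
    split = split_indices(n, np.random.default_rng(ss.spawn(1)[0]))
    return cases, split
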