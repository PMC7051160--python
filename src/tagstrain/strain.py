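"""Green-strain computation from tracked landmark grids.

Radial strain of spoke k compares the ring-1..ring-7 separation at frame t
against frame 1; circumferential strain of a ring compares the 24 closed-loop
chords between consecutive spokes against frame 1.  Whole-slice values are
spoke averages; the reported slice circumferential strain comes from the
midwall ring.
"""

from __future__ import annotations

import numpy as np

from .types import (
    LandmarkGrid,
    N_SPOKES,
    RING_MIDWALL,
    RING_SUBENDO,
    RING_SUBEPI,
    StrainCurves,
)


def green_strain(L_t, L_0, *, formula: str = "green"):
    """Strain of a segment of reference length ``L_0`` and current length ``L_t``.

    Default is the Green (Lagrangian) finite-strain measure
    ((L_t/L_0)^2 - 1) / 2; ``formula='linear'`` switches to the engineering
    strain L_t/L_0 - 1 for sensitivity checks.
    """
    L_t = np.asarray(L_t, dtype=float)
    L_0 = np.asarray(L_0, dtype=float)
    if np.any(L_0 <= 0):
        raise ValueError("reference length must be positive")
    if np.any(L_t < 0):
        raise ValueError("length must be nonnegative")
    ratio = L_t / L_0
    if formula == "green":
        return (ratio**2 - 1.0) / 2.0
    if formula == "linear":
        return ratio - 1.0
    raise ValueError("formula must be 'green' or 'linear'")


def radial_distances(grid: LandmarkGrid, t: int) -> np.ndarray:
    """Endo-to-epi landmark separation per spoke (mm) at 1-based frame ``t``."""
    f = grid.frame(t)
    return np.linalg.norm(f[-1] - f[0], axis=-1)


def circumferential_distances(grid: LandmarkGrid, t: int, ring: int) -> np.ndarray:
    """24 closed-loop chord lengths of 1-based ``ring`` at frame ``t`` (mm)."""
    if not 1 <= ring <= grid.coords.shape[1]:
        raise ValueError(f"ring {ring} out of range")
    pts = grid.frame(t)[ring - 1]
    return np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=-1)


def slice_strain_curves(grid: LandmarkGrid, *, valid=None,
                        formula: str = "green") -> StrainCurves:
    """Per-frame slice-averaged strains with frame 1 as the reference.

    eps_R averages the Green strain of the 24 transmural segments; ring
    circumferential strains average the 24 chord strains of that ring.  The
    whole-slice eps_C is the midwall value; eps_C_avg averages all 7 rings.
    """
    T = grid.n_frames
    if T < 2:
        raise ValueError("need at least 2 frames")
    if valid is None:
        valid = np.ones(T, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if not valid[0]:
        raise ValueError("reference frame (frame 1) must be valid")

    dR0 = radial_distances(grid, 1)
    if np.any(dR0 <= 0):
        raise ValueError("degenerate reference radial distances")
    n_rings = grid.coords.shape[1]
    dC0 = np.stack([circumferential_distances(grid, 1, r + 1) for r in range(n_rings)])
    if np.any(dC0 <= 0):
        raise ValueError("degenerate reference chord lengths")

    eps_R = np.zeros(T)
    eps_C_rings = np.zeros((n_rings, T))
    for t in range(1, T + 1):
        if not valid[t - 1]:
            eps_R[t - 1] = np.nan
            eps_C_rings[:, t - 1] = np.nan
            continue
        eps_R[t - 1] = np.mean(green_strain(radial_distances(grid, t), dR0,
                                            formula=formula))
        for r in range(n_rings):
            eps_C_rings[r, t - 1] = np.mean(
                green_strain(circumferential_distances(grid, t, r + 1), dC0[r],
                             formula=formula))

    curves = StrainCurves(
        eps_R=eps_R,
        eps_C=eps_C_rings[RING_MIDWALL - 1].copy(),
        eps_C_subendo=eps_C_rings[RING_SUBENDO - 1].copy(),
        eps_C_mid=eps_C_rings[RING_MIDWALL - 1].copy(),
        eps_C_subepi=eps_C_rings[RING_SUBEPI - 1].copy(),
        eps_C_avg=eps_C_rings.mean(axis=0),
        es_frame=1,
        valid=valid,
    )
    curves.es_frame = detect_es(curves)
    return curves


def detect_es(curves: StrainCurves) -> int:
    """End-systolic frame = argmin of midwall circumferential strain.

    Maximum contraction corresponds to the most negative midwall eps_C; ties
    resolve to the earliest frame.  Only valid frames are considered.
    """
    valid = np.asarray(curves.valid, dtype=bool)
    if not valid.any():
        raise ValueError("no valid frames")
    vals = np.where(valid, curves.eps_C_mid, np.inf)
    return int(np.argmin(vals)) + 1
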