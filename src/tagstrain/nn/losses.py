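"""Losses and accuracy metrics for the localization and tracking networks.

The composite tracking loss averages, over valid frames, the landmark-position
mean squared error plus omega times the squared errors of the slice-averaged
radial and midwall circumferential Green strains (frame 1 as reference).  Its
gradient with respect to the predicted grid is derived analytically so the
loss is usable inside the numpy training loop; a finite-difference check lives
in the test suite.
"""

from __future__ import annotations

import numpy as np

from ..types import BBox, N_RINGS, N_SPOKES, RING_MIDWALL


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    if a.area <= 0 or b.area <= 0:
        raise ValueError("zero-area box")
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def localizer_loss(pred_corners, truth_corners):
    """Mean squared error over the 4 bounding-box corner coordinates."""
    p = np.asarray(pred_corners, dtype=float)
    t = np.asarray(truth_corners, dtype=float)
    if p.shape != t.shape:
        raise ValueError("corner arrays must have matching shapes")
    return float(np.mean((p - t) ** 2))


def _mean_strains_with_grad(grid: np.ndarray):
    """Slice-averaged radial and midwall circumferential Green strain per frame
    plus the quantities needed for their gradients.

    grid : (T, 7, 24, 2).  Returns (eps_R, eps_C, cacheR, cacheC) where the
    caches hold squared segment lengths and difference vectors.
    """
    p1 = grid[:, 0]              # (T, 24, 2) innermost ring
    p7 = grid[:, -1]             # outermost ring
    vR = p7 - p1
    uR = (vR**2).sum(-1)         # squared radial lengths (T, 24)
    mid = grid[:, RING_MIDWALL - 1]
    vC = np.roll(mid, -1, axis=1) - mid
    uC = (vC**2).sum(-1)
    if np.any(uR[0] <= 0) or np.any(uC[0] <= 0):
        raise ValueError("degenerate reference segment in strain computation")
    eps_R = ((uR / uR[0]) - 1.0).mean(axis=1) / 2.0
    eps_C = ((uC / uC[0]) - 1.0).mean(axis=1) / 2.0
    return eps_R, eps_C, (vR, uR), (vC, uC)


def composite_loss(pred: np.ndarray, truth: np.ndarray, omega: float,
                   frame_mask=None, return_grad: bool = False):
    """Position + strain tracking loss for one slice.

    pred, truth : (T, 7, 24, 2) landmark grids in any consistent length unit.
    ``frame_mask`` marks frames contributing to the loss; frame 1 must be
    valid because it anchors the strain reference.  With ``return_grad`` the
    analytic gradient with respect to ``pred`` is also returned.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.shape[1:] != (N_RINGS, N_SPOKES, 2):
        raise ValueError("grids must share shape (T, 7, 24, 2)")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    T = pred.shape[0]
    mask = np.ones(T, bool) if frame_mask is None else np.asarray(frame_mask, bool)
    if not mask[0]:
        raise ValueError("frame 1 must be valid (strain reference)")
    nv = int(mask.sum())
    n_lm = N_RINGS * N_SPOKES

    diff = pred - truth
    mse_t = (diff**2).sum(-1).reshape(T, -1).mean(axis=1)  # mean sq distance / frame

    eR_p, eC_p, (vR, uR), (vC, uC) = _mean_strains_with_grad(pred)
    eR_t, eC_t, _, _ = _mean_strains_with_grad(truth)
    dR = eR_p - eR_t
    dC = eC_p - eC_t

    loss = float(np.sum(mask * (mse_t + omega * (dR**2 + dC**2))) / nv)
    if not return_grad:
        return loss

    grad = np.zeros_like(pred)
    grad += (2.0 / (nv * n_lm)) * mask[:, None, None, None] * diff

    # strain terms: d eps / d u_tk = 1/(24 * 2 * u_1k); d eps / d u_1k gathers
    # -u_tk / (24 * 2 * u_1k^2) over frames t; u = |v|^2 so du/dp = +/- 2 v.
    cR = (2.0 * omega / nv) * mask * dR     # (T,)
    cC = (2.0 * omega / nv) * mask * dC
    for (c, (v, u), sel) in ((cR, (vR, uR), "radial"), (cC, (vC, uC), "circ")):
        du = c[:, None] / (2.0 * N_SPOKES * u[0][None, :])      # dL/du_tk
        du[0] += -(c[:, None] * u / (2.0 * N_SPOKES * u[0][None, :]**2)).sum(axis=0)
        dv = 2.0 * du[..., None] * v                             # dL/dv_tk
        if sel == "radial":
            grad[:, -1] += dv
            grad[:, 0] -= dv
        else:
            grad[:, RING_MIDWALL - 1] -= dv
            grad[:, RING_MIDWALL - 1] += np.roll(dv, 1, axis=1)
    return loss, grad
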