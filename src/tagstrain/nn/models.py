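"""Localization and landmark-tracking networks with their training loops.

The localizer is a small convolutional regressor: an end-diastolic frame in,
four bounding-box corner coordinates out (two-corner encoding of an
axis-aligned box).  The tracker combines a shared-weight per-frame
convolutional feature extractor with an LSTM over the 20 frames and a
per-frame regression head emitting the 168 landmark coordinates; it is
trained end to end against the composite position + strain loss.

Both are trained with Adam under a step-decay learning-rate schedule
(factor 1/sqrt(2)); the localizer decays every 5th epoch after the 10th, the
tracker every 10th epoch.  Architectural widths are configurable through
``TrainConfig.arch`` so the same code runs desk-scale reduced models and
near-protocol sizes (1024-length frame features, 1024 LSTM nodes).
"""

from __future__ import annotations

import json

import numpy as np

from ..geometry import normalize_intensity
from ..types import BBox, N_LANDMARKS, N_RINGS, N_SPOKES, TrainConfig
from .layers import (
    Adam,
    AvgPool2d,
    BatchNorm2d,
    Conv2d,
    Dense,
    Dropout,
    Flatten,
    LeakyReLU,
    LSTM,
    ReLU,
    Sequential,
)
from .losses import composite_loss, iou, localizer_loss

LOCALIZER_ARCH = {"pool": 8, "channels": (8, 16, 32), "fc": 64, "input": 256}
TRACKER_ARCH = {"pool": 4, "channels": (8, 16, 32), "feature": 128,
                "hidden": 128, "input": 128}


def default_localizer_config(**kw) -> TrainConfig:
    kw.setdefault("learning_rate", 1e-3)
    kw.setdefault("schedule", (2 ** -0.5, 5, 10))
    return TrainConfig(**kw)


def default_tracker_config(**kw) -> TrainConfig:
    kw.setdefault("learning_rate", 1e-4)
    kw.setdefault("schedule", (2 ** -0.5, 10, 0))
    return TrainConfig(**kw)


def _conv_stack(arch, rng, act, batchnorm):
    """Pool -> repeated stride-2 conv blocks; returns (layers, flat_dim)."""
    layers = [AvgPool2d(arch["pool"])]
    side = arch["input"] // arch["pool"]
    c_prev = 1
    for c in arch["channels"]:
        layers.append(Conv2d(c_prev, c, 3, 2, 1, rng))
        if batchnorm:
            layers.append(BatchNorm2d(c))
        layers.append(act())
        side //= 2
        c_prev = c
    layers.append(Flatten())
    return layers, side * side * c_prev


class LocalizerModel:
    """Bounding-box regression network (image -> 4 corner coordinates)."""

    def __init__(self, config: TrainConfig):
        self.config = config
        self.arch = {**LOCALIZER_ARCH, **config.arch}
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        convs, flat = _conv_stack(self.arch, rng, ReLU, batchnorm=True)
        self.net = Sequential(
            *convs,
            Dense(flat, self.arch["fc"], rng),
            ReLU(),
            Dropout(0.2, self._dropout_rng),
            Dense(self.arch["fc"], 4, rng),
        )
        # regression output starts near the image-center prior (normalized 0.5)
        self.net.layers[-1].W.v *= 0.01
        self.net.layers[-1].b.v[:] = 0.5
        self.size = self.arch["input"]
        self.trained = False
        self.history: list = []

    def forward_corners(self, frames: np.ndarray, train: bool = False) -> np.ndarray:
        """Normalized corner predictions for a (N, S, S) frame batch."""
        x = normalize_intensity(frames)[:, None, :, :]
        return self.net.forward(x, train)

    def predict(self, frame: np.ndarray) -> BBox:
        """Predict the myocardial ROI box for one (S, S) end-diastolic frame."""
        if not self.trained:
            raise RuntimeError("localizer has not been trained")
        c = self.forward_corners(frame[None], train=False)[0] * self.size
        x0, x1 = sorted((c[0], c[2]))
        y0, y1 = sorted((c[1], c[3]))
        x0, y0 = max(x0, 0.0), max(y0, 0.0)
        x1, y1 = min(x1, float(self.size)), min(y1, float(self.size))
        if x1 - x0 < 2 or y1 - y0 < 2:  # degenerate prediction: fall back wide
            x0, y0, x1, y1 = 0.0, 0.0, float(self.size), float(self.size)
        return BBox(x0, y0, x1, y1)

    def save(self, path):
        _save_checkpoint(path, self, kind="localizer")

    @staticmethod
    def load(path) -> "LocalizerModel":
        return _load_checkpoint(path, expect_kind="localizer")


def train_localizer(dataset, config: TrainConfig | None = None,
                    val_set=None) -> LocalizerModel:
    """Train the ROI localizer on (ED frame, truth BBox) pairs.

    Loss is the mean squared error of the (normalized) box corners.  Logs a
    per-epoch record with training loss and, when a validation set is given,
    mean validation IoU.
    """
    if not dataset:
        raise ValueError("empty dataset")
    config = config or default_localizer_config()
    model = LocalizerModel(config)
    S = model.size
    frames = np.stack([d[0] for d in dataset]).astype(float)
    targets = np.stack([d[1].corners() for d in dataset]) / S
    opt = Adam(model.net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 2)
    n = len(dataset)
    for epoch in range(1, config.epochs + 1):
        lr = config.lr_at_epoch(epoch)
        order = rng.permutation(n)
        losses = []
        for b0 in range(0, n, config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            pred = model.forward_corners(frames[idx], train=True)
            err = pred - targets[idx]
            losses.append(float(np.mean(err**2)))
            model.net.backward(2.0 * err / err.size)
            opt.step(lr)
        rec = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses))}
        if val_set:
            model.trained = True
            ious = [iou(model.predict(f), box) for f, box in val_set]
            rec["val_iou"] = float(np.mean(ious))
        model.history.append(rec)
    model.trained = True
    return model


class TrackerModel:
    """Combined per-frame CNN + LSTM landmark tracking network."""

    def __init__(self, config: TrainConfig):
        self.config = config
        self.arch = {**TRACKER_ARCH, **config.arch}
        rng = np.random.default_rng(config.seed)
        convs, flat = _conv_stack(self.arch, rng, lambda: LeakyReLU(0.1),
                                  batchnorm=False)
        self.cnn = Sequential(*convs,
                              Dense(flat, self.arch["feature"], rng),
                              LeakyReLU(0.1))
        self.lstm = LSTM(self.arch["feature"], self.arch["hidden"], rng)
        self.post = ReLU()
        self.head = Dense(self.arch["hidden"], N_LANDMARKS * 2, rng)
        self.head.W.v *= 0.01
        # start from a neutral annular layout centered in the crop so the
        # reference inter-landmark distances of the strain terms are
        # well-conditioned from the first iteration
        rho = (0.18 + 0.15 * np.arange(1, N_RINGS + 1) / (N_RINGS + 1))[:, None]
        ang = 2 * np.pi * np.arange(N_SPOKES)[None, :] / N_SPOKES
        layout = np.stack([0.5 + rho * np.cos(ang), 0.5 + rho * np.sin(ang)],
                          axis=-1)
        self.head.b.v[:] = layout.ravel()
        self.size = self.arch["input"]
        self.trained = False
        self.history: list = []

    def params(self):
        return (self.cnn.params() + self.lstm.params() + self.head.params())

    def forward(self, cines: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, T, S, S) cines -> (N, T, 168, 2) normalized coordinates."""
        N, T, S, _ = cines.shape
        x = normalize_intensity(cines).reshape(N * T, 1, S, S)
        feat = self.cnn.forward(x, train)                      # (N*T, F)
        seq = feat.reshape(N, T, -1).transpose(1, 0, 2)        # (T, N, F)
        h = self.post.forward(self.lstm.forward(seq, train), train)
        y = self.head.forward(h.reshape(T * N, -1), train)     # (T*N, 336)
        return y.reshape(T, N, N_LANDMARKS, 2).transpose(1, 0, 2, 3)

    def backward(self, dout: np.ndarray) -> None:
        N, T = dout.shape[:2]
        dy = dout.transpose(1, 0, 2, 3).reshape(T * N, N_LANDMARKS * 2)
        dh = self.head.backward(dy).reshape(T, N, -1)
        dseq = self.lstm.backward(self.post.backward(dh))
        dfeat = dseq.transpose(1, 0, 2).reshape(N * T, -1)
        self.cnn.backward(dfeat)

    def predict_grid(self, cine: np.ndarray) -> np.ndarray:
        """One (T, S, S) preprocessed cine -> (T, 7, 24, 2) cropped-pixel grid."""
        if not self.trained:
            raise RuntimeError("tracker has not been trained")
        out = self.forward(cine[None], train=False)[0] * self.size
        return out.reshape(cine.shape[0], N_RINGS, N_SPOKES, 2)

    def save(self, path):
        _save_checkpoint(path, self, kind="tracker")

    @staticmethod
    def load(path) -> "TrackerModel":
        return _load_checkpoint(path, expect_kind="tracker")


def _as_grid_array(grid) -> np.ndarray:
    return grid.coords if hasattr(grid, "coords") else np.asarray(grid, float)


def train_tracker(dataset, config: TrainConfig | None = None,
                  val_set=None) -> TrackerModel:
    """Train the tracker end to end on (cropped cine, truth grid, frame mask).

    ``dataset`` items: (cine (T, S, S), truth landmark grid (T, 7, 24, 2) in
    cropped pixel coordinates, optional boolean frame mask).  The loss is the
    composite position + strain objective with weight ``config.omega``.
    """
    if not dataset:
        raise ValueError("empty dataset")
    config = config or default_tracker_config()
    model = TrackerModel(config)
    S = model.size
    T = dataset[0][0].shape[0]
    cines = np.stack([d[0] for d in dataset]).astype(float)
    grids = np.stack([_as_grid_array(d[1]) for d in dataset]) / S  # normalized
    masks = np.stack([np.asarray(d[2], bool) if len(d) > 2 and d[2] is not None
                      else np.ones(T, bool) for d in dataset])
    if grids.shape[1:] != (T, N_RINGS, N_SPOKES, 2):
        raise ValueError("truth grids inconsistent with cine frame count")
    opt = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 2)
    n = len(dataset)

    def _epoch_loss(cs, gs, ms, train_flag):
        pred = model.forward(cs, train_flag)
        total, dpred = 0.0, np.zeros_like(pred)
        for i in range(len(cs)):
            li, gi = composite_loss(
                pred[i].reshape(T, N_RINGS, N_SPOKES, 2), gs[i],
                config.omega, ms[i], return_grad=True)
            total += li
            dpred[i] = gi.reshape(T, N_LANDMARKS, 2) / len(cs)
        return total / len(cs), pred, dpred

    for epoch in range(1, config.epochs + 1):
        lr = config.lr_at_epoch(epoch)
        order = rng.permutation(n)
        losses = []
        for b0 in range(0, n, config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            loss, _, dpred = _epoch_loss(cines[idx], grids[idx], masks[idx], True)
            losses.append(loss)
            model.backward(dpred)
            opt.step(lr)
        rec = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses))}
        if val_set:
            vc = np.stack([d[0] for d in val_set]).astype(float)
            vg = np.stack([_as_grid_array(d[1]) for d in val_set]) / S
            vm = np.stack([np.asarray(d[2], bool) if len(d) > 2 and d[2] is not None
                           else np.ones(T, bool) for d in val_set])
            vl, _, _ = _epoch_loss(vc, vg, vm, False)
            rec["val_loss"] = float(vl)
        model.history.append(rec)
    model.trained = True
    return model


def predict_landmarks(model: TrackerModel, cine: np.ndarray,
                      transform=None) -> np.ndarray:
    """Track landmarks on a preprocessed cine.

    Returns the (T, 7, 24, 2) grid in cropped pixel coordinates, or in mm of
    the original image plane when a CropTransform is supplied.
    """
    grid = model.predict_grid(np.asarray(cine, dtype=float))
    if transform is not None:
        grid = transform.cropped_to_mm(grid)
    return grid


def _save_checkpoint(path, model, kind: str) -> None:
    cfg = {
        "kind": kind,
        "arch": model.arch,
        "seed": model.config.seed,
        "omega": model.config.omega,
        "learning_rate": model.config.learning_rate,
        "schedule": list(model.config.schedule),
        "batch_size": model.config.batch_size,
        "epochs": model.config.epochs,
        "trained": model.trained,
    }
    params = model.net.params() if kind == "localizer" else model.params()
    arrays = {f"p{i}": p.v for i, p in enumerate(params)}
    if kind == "localizer":
        bns = [l for l in model.net.layers if isinstance(l, BatchNorm2d)]
        for i, bn in enumerate(bns):
            arrays[f"bn_mean{i}"] = bn.run_mean
            arrays[f"bn_var{i}"] = bn.run_var
    np.savez(path, cfg=np.array(json.dumps(cfg)), **arrays)


def _load_checkpoint(path, expect_kind: str):
    data = np.load(path, allow_pickle=False)
    cfg = json.loads(str(data["cfg"]))
    if cfg["kind"] != expect_kind:
        raise ValueError(f"checkpoint is a {cfg['kind']}, expected {expect_kind}")
    config = TrainConfig(
        learning_rate=cfg["learning_rate"], schedule=tuple(cfg["schedule"]),
        batch_size=cfg["batch_size"], epochs=cfg["epochs"],
        omega=cfg["omega"], seed=cfg["seed"], arch=cfg["arch"])
    cls = LocalizerModel if expect_kind == "localizer" else TrackerModel
    model = cls(config)
    params = model.net.params() if expect_kind == "localizer" else model.params()
    for i, p in enumerate(params):
        p.v[...] = data[f"p{i}"]
    if expect_kind == "localizer":
        bns = [l for l in model.net.layers if isinstance(l, BatchNorm2d)]
        for i, bn in enumerate(bns):
            bn.run_mean = data[f"bn_mean{i}"]
            bn.run_var = data[f"bn_var{i}"]
    model.trained = bool(cfg["trained"])
    return model
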