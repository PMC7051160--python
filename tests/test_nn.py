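"""Networks and losses: IoU, composite loss + gradient, layer backprop,
training determinism and capacity checks."""

import numpy as np
import pytest

from tagstrain.nn.layers import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Dense,
    Flatten,
    LSTM,
    ReLU,
    Sequential,
)
from tagstrain.nn.losses import composite_loss, iou, localizer_loss
from tagstrain.nn.models import (
    TrackerModel,
    default_localizer_config,
    default_tracker_config,
    predict_landmarks,
    train_localizer,
    train_tracker,
)
from tagstrain.types import BBox, TrainConfig


class TestIoU:
    def test_identical_boxes(self):
        b = BBox(3, 4, 20, 30)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BBox(0, 0, 10, 10), BBox(20, 20, 30, 30)) == 0.0

    def test_half_overlap_worked_example(self):
        assert iou(BBox(0, 0, 10, 10), BBox(5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_rasterization_oracle(self):
        """IoU equals the pixel-count ratio on integer boxes."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            xs = np.sort(rng.choice(64, 2, replace=False))
            ys = np.sort(rng.choice(64, 2, replace=False))
            xs2 = np.sort(rng.choice(64, 2, replace=False))
            ys2 = np.sort(rng.choice(64, 2, replace=False))
            a = BBox(xs[0], ys[0], xs[1], ys[1])
            b = BBox(xs2[0], ys2[0], xs2[1], ys2[1])
            ra = np.zeros((64, 64), bool)
            rb = np.zeros((64, 64), bool)
            ra[ys[0]:ys[1], xs[0]:xs[1]] = True
            rb[ys2[0]:ys2[1], xs2[0]:xs2[1]] = True
            oracle = (ra & rb).sum() / (ra | rb).sum()
            assert abs(iou(a, b) - oracle) < 1e-6


class TestLocalizerLoss:
    def test_zero_at_truth(self):
        c = np.array([1.0, 2.0, 3.0, 4.0])
        assert localizer_loss(c, c) == 0.0

    def test_constant_offset(self):
        c = np.array([1.0, 2.0, 3.0, 4.0])
        assert localizer_loss(c + 2.0, c) == pytest.approx(4.0)

    def test_matches_independent_arithmetic(self):
        rng = np.random.default_rng(1)
        p, t = rng.normal(size=4), rng.normal(size=4)
        expect = sum((pi - ti) ** 2 for pi, ti in zip(p, t)) / 4
        assert localizer_loss(p, t) == pytest.approx(expect, abs=1e-12)


class TestCompositeLoss:
    def _grids(self, seed=0, T=2):
        rng = np.random.default_rng(seed)
        radii = np.linspace(20.0, 35.0, 7)
        th = 2 * np.pi * np.arange(24) / 24
        unit = np.stack([np.cos(th), np.sin(th)], axis=-1)
        truth = np.repeat((radii[:, None, None] * unit)[None], T, axis=0)
        truth[1:] *= 0.9  # uniform contraction after the reference frame
        pred = truth + rng.normal(0, 0.5, truth.shape)
        return pred, truth

    def test_zero_at_truth_and_nonnegative(self):
        pred, truth = self._grids()
        assert composite_loss(truth, truth, 5.0) == 0.0
        assert composite_loss(pred, truth, 5.0) > 0.0

    def test_omega_zero_is_position_mse(self):
        pred, truth = self._grids()
        expect = np.mean(((pred - truth) ** 2).sum(-1))
        assert composite_loss(pred, truth, 0.0) == pytest.approx(expect, abs=1e-12)

    def test_matches_step_by_step_arithmetic(self):
        """Independent brute-force evaluation on a 2-frame grid."""
        pred, truth = self._grids(seed=7)
        omega = 5.0

        def strains(grid):
            eR, eC = [], []
            for t in range(grid.shape[0]):
                vals = []
                for k in range(24):
                    d_t = np.hypot(*(grid[t, 6, k] - grid[t, 0, k]))
                    d_0 = np.hypot(*(grid[0, 6, k] - grid[0, 0, k]))
                    vals.append(((d_t / d_0) ** 2 - 1) / 2)
                eR.append(sum(vals) / 24)
                vals = []
                for k in range(24):
                    k2 = (k + 1) % 24
                    d_t = np.hypot(*(grid[t, 3, k2] - grid[t, 3, k]))
                    d_0 = np.hypot(*(grid[0, 3, k2] - grid[0, 3, k]))
                    vals.append(((d_t / d_0) ** 2 - 1) / 2)
                eC.append(sum(vals) / 24)
            return eR, eC

        eR_p, eC_p = strains(pred)
        eR_t, eC_t = strains(truth)
        expect = 0.0
        for t in range(2):
            mse = 0.0
            for r in range(7):
                for k in range(24):
                    mse += ((pred[t, r, k, 0] - truth[t, r, k, 0]) ** 2
                            + (pred[t, r, k, 1] - truth[t, r, k, 1]) ** 2)
            mse /= 168
            expect += mse + omega * ((eR_p[t] - eR_t[t]) ** 2
                                     + (eC_p[t] - eC_t[t]) ** 2)
        expect /= 2
        assert composite_loss(pred, truth, omega) == pytest.approx(expect,
                                                                   abs=1e-10)

    def test_gradient_matches_finite_differences(self):
        pred, truth = self._grids(seed=3, T=3)
        mask = np.array([True, True, False])
        loss, grad = composite_loss(pred, truth, 5.0, mask, return_grad=True)
        rng = np.random.default_rng(0)
        eps = 1e-6
        for _ in range(60):
            i = tuple(rng.integers(0, s) for s in pred.shape)
            p1, p2 = pred.copy(), pred.copy()
            p1[i] += eps
            p2[i] -= eps
            num = (composite_loss(p1, truth, 5.0, mask)
                   - composite_loss(p2, truth, 5.0, mask)) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_invalid_reference_frame_rejected(self):
        pred, truth = self._grids()
        with pytest.raises(ValueError):
            composite_loss(pred, truth, 5.0, np.array([False, True]))


def _numeric_param_check(net, x, tgt, train=True, tol=5e-3, n_probe=40):
    y = net.forward(x, train)
    net.backward(y - tgt)
    rng = np.random.default_rng(0)
    for p in net.params():
        flat_v = p.v.reshape(-1)
        flat_g = p.g.reshape(-1)
        for j in rng.choice(flat_v.size, min(n_probe, flat_v.size), replace=False):
            old = flat_v[j]
            eps = 1e-6
            flat_v[j] = old + eps
            l1 = 0.5 * np.sum((net.forward(x, train) - tgt) ** 2)
            flat_v[j] = old - eps
            l2 = 0.5 * np.sum((net.forward(x, train) - tgt) ** 2)
            flat_v[j] = old
            num = (l1 - l2) / (2 * eps)
            assert flat_g[j] == pytest.approx(num, rel=tol, abs=1e-6)


class TestLayerBackprop:
    def test_conv_bn_dense_stack(self):
        rng = np.random.default_rng(0)
        net = Sequential(Conv2d(1, 2, 3, 2, 1, rng), BatchNorm2d(2), ReLU(),
                         Flatten(), Dense(2 * 4 * 4, 3, rng))
        x = rng.normal(size=(4, 1, 8, 8))
        _numeric_param_check(net, x, rng.normal(size=(4, 3)))

    def test_lstm_bptt(self):
        rng = np.random.default_rng(1)
        lstm = LSTM(3, 4, rng)
        x = rng.normal(size=(5, 2, 3))
        _numeric_param_check(lstm, x, rng.normal(size=(5, 2, 4)), tol=1e-3)


def _tiny_pairs(n=6, seed=0):
    from tagstrain.phantom import make_dataset
    cases, _ = make_dataset(n, seed=seed)
    return cases


class TestTraining:
    def test_localizer_overfits_single_case(self):
        case = _tiny_pairs(1)[0]
        cfg = default_localizer_config(epochs=60, batch_size=1, seed=0,
                                       schedule=(1.0, 5, 10))
        model = train_localizer([(case.cine.frames[0], case.bbox)], cfg)
        assert model.history[-1]["train_loss"] < 1e-2

    def test_localizer_deterministic_trace(self):
        pairs = [(c.cine.frames[0], c.bbox) for c in _tiny_pairs(4)]
        cfg = default_localizer_config(epochs=4, batch_size=2, seed=5)
        t1 = [h["train_loss"] for h in train_localizer(pairs, cfg).history]
        t2 = [h["train_loss"] for h in train_localizer(pairs, cfg).history]
        assert t1 == t2

    def test_tracker_deterministic_trace(self):
        from conftest import prep_tracker_item
        items = [prep_tracker_item(c)[0] for c in _tiny_pairs(3)]
        cfg = default_tracker_config(epochs=3, batch_size=2, seed=5,
                                     learning_rate=1e-3)
        t1 = [h["train_loss"] for h in train_tracker(items, cfg).history]
        t2 = [h["train_loss"] for h in train_tracker(items, cfg).history]
        assert t1 == t2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_localizer([], default_localizer_config())
        with pytest.raises(ValueError):
            train_tracker([], default_tracker_config())

    def test_untrained_model_refuses_prediction(self):
        model = TrackerModel(default_tracker_config())
        with pytest.raises(RuntimeError):
            model.predict_grid(np.zeros((20, 128, 128)))


class TestPredictLandmarks:
    def test_output_shape_and_inference_determinism(self, study):
        tracker = study["tracker"]
        cine = study["items"][0][0]
        a = tracker.predict_grid(cine)
        b = tracker.predict_grid(cine)
        assert a.shape == (20, 7, 24, 2)
        assert np.array_equal(a, b)

    def test_landmarks_in_dilated_myocardium(self, study):
        """Predicted landmarks should fall inside a modestly dilated wall."""
        tracker = study["tracker"]
        split = study["split"]
        ok, total = 0, 0
        for i in split["test"]:
            cine, _, _ = study["items"][i]
            tf = study["transforms"][i]
            case = study["cases"][i]
            mm = predict_landmarks(tracker, cine, tf)
            spec = case.spec
            for t in range(1, spec.n_frames + 1):
                from tagstrain.phantom import deformation_map
                d = deformation_map(spec, t)
                r = np.linalg.norm(mm[t - 1] - np.asarray(spec.center), axis=-1)
                r_endo = np.sqrt(max(spec.R_endo**2 - d.a, 0.0))
                r_epi = np.sqrt(spec.R_epi**2 - d.a)
                ok += np.sum((r > r_endo - 3.0) & (r < r_epi + 3.0))
                total += r.size
        assert ok / total >= 0.95
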