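"""Shared fixtures: phantom specs, a desk-scale training study, checkpoints.

The session-scoped ``study`` fixture generates a 200-case phantom dataset,
trains the reduced-width localizer and tracker on its training split, and
exposes the held-out split plus saved checkpoints; several tests (learning
benchmarks, end-to-end pipeline) share it so the expensive training happens
once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from tagstrain import io as tio
from tagstrain.geometry import crop_resample, pad_and_fix_frames
from tagstrain.nn.models import (
    default_localizer_config,
    default_tracker_config,
    train_localizer,
    train_tracker,
)
from tagstrain.phantom import make_contours, make_dataset, render_cine
from tagstrain.types import PhantomSpec


@pytest.fixture(scope="session")
def clean_spec() -> PhantomSpec:
    """Noise-free phantom spec with the default acquisition geometry."""
    return PhantomSpec(noise_sd=0.0)


@pytest.fixture(scope="session")
def circle_contours(clean_spec):
    return make_contours(clean_spec)


@pytest.fixture(scope="session")
def clean_truth(clean_spec):
    return render_cine(clean_spec)


def prep_tracker_item(case):
    """Crop a phantom with its truth box; landmarks to cropped pixel coords."""
    padded, _ = pad_and_fix_frames(case.cine)
    cropped, tf = crop_resample(padded, case.bbox)
    grid_px = tf.orig_px_to_cropped(case.grid.coords / case.cine.pixel_spacing)
    return (cropped.frames, grid_px, padded.valid_frames), tf


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """200 phantoms, 72/18/10 split, trained reduced models + checkpoints."""
    root = tmp_path_factory.mktemp("study")
    cases, split = make_dataset(200, seed=11)

    pairs = [(c.cine.frames[0], c.bbox) for c in cases]
    localizer = train_localizer(
        [pairs[i] for i in split["train"]],
        default_localizer_config(epochs=30, batch_size=16, seed=1))

    items, transforms = [], []
    for c in cases:
        item, tf = prep_tracker_item(c)
        items.append(item)
        transforms.append(tf)
    tracker = train_tracker(
        [items[i] for i in split["train"]],
        default_tracker_config(epochs=60, batch_size=8, seed=1,
                               learning_rate=1e-3))

    loc_path = root / "localizer.npz"
    trk_path = root / "tracker.npz"
    localizer.save(loc_path)
    tracker.save(trk_path)

    case_dirs = []
    for i in split["test"]:
        case_dirs.append(tio.write_phantom_case(cases[i], root / f"case_{i:04d}"))

    return {
        "cases": cases,
        "split": split,
        "pairs": pairs,
        "items": items,
        "transforms": transforms,
        "localizer": localizer,
        "tracker": tracker,
        "localizer_path": loc_path,
        "tracker_path": trk_path,
        "test_case_dirs": case_dirs,
    }
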