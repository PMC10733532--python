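"""Shared fixtures: tiny model configs and mock dataset directory trees."""

import numpy as np
import pytest
import imageio.v3 as iio

from naunet.models import ModelConfig

TINY_SCHEDULE = (8, 16, 32, 64, 128)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    return ModelConfig(variant="nau_net", channel_schedule=TINY_SCHEDULE, seed=7)


def _write_img(path, shape, rng, value=None):
    arr = (rng.integers(0, 255, shape).astype(np.uint8)
           if value is None else np.full(shape, value, dtype=np.uint8))
    iio.imwrite(path, arr)
    return arr


def _write_mask(path, shape, rng):
    arr = (rng.random(shape) > 0.7).astype(np.uint8) * 255
    iio.imwrite(path, arr)
    return arr


@pytest.fixture
def drive_tree(tmp_path):
    """Mock DRIVE layout: 20 training + 20 test images with manual masks."""
    rng = np.random.default_rng(0)
    root = tmp_path / "drive"
    for split, ids in (("training", range(21, 41)), ("test", range(1, 21))):
        (root / split / "images").mkdir(parents=True)
        (root / split / "1st_manual").mkdir(parents=True)
        for i in ids:
            _write_img(root / split / "images" / f"{i:02d}_{split}.tif",
                       (16, 16, 3), rng)
            _write_mask(root / split / "1st_manual" / f"{i:02d}_manual1.gif",
                        (16, 16), rng)
    return root


@pytest.fixture
def hrf_tree(tmp_path):
    """Mock HRF layout: 15 healthy + 15 DR (+ 15 glaucoma, to be excluded)."""
    rng = np.random.default_rng(1)
    root = tmp_path / "hrf"
    (root / "images").mkdir(parents=True)
    (root / "manual1").mkdir(parents=True)
    for kind in ("h", "dr", "g"):
        for i in range(1, 16):
            _write_img(root / "images" / f"{i:02d}_{kind}.jpg", (16, 16, 3), rng)
            _write_mask(root / "manual1" / f"{i:02d}_{kind}.tif", (16, 16), rng)
    return root


@pytest.fixture
def chasedb_tree(tmp_path):
    """Mock CHASE_DB1 layout: 28 images with two expert annotations each."""
    rng = np.random.default_rng(2)
    root = tmp_path / "chasedb"
    root.mkdir()
    for subj in range(1, 15):
        for eye in "LR":
            stem = f"Image_{subj:02d}{eye}"
            _write_img(root / f"{stem}.jpg", (16, 16, 3), rng)
            _write_mask(root / f"{stem}_1stHO.png", (16, 16), rng)
            _write_mask(root / f"{stem}_2ndHO.png", (16, 16), rng)
    return root
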