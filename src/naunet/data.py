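"""Fundus image I/O, preprocessing and synthetic-fundus generation.

Readers understand the directory layouts of the three public retinal-vessel
datasets (DRIVE, HRF, CHASE_DB1) and a simple ``synthetic`` layout written by
:func:`write_synthetic_dataset`.  The synthetic generator draws a circular
field of view containing a dark recursive branching vascular tree on a
textured reddish background, returning the image together with the exact
binary mask of the drawn tree, so that the whole pipeline is testable with
no downloads.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk
from skimage.transform import resize

SOURCES = ("drive", "hrf", "chasedb", "synthetic")
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

_IMG_EXT = (".tif", ".tiff", ".jpg", ".jpeg", ".png", ".gif", ".JPG")


@dataclass
class FundusSample:
    """One fundus photograph with its binary vessel mask."""

    image: np.ndarray        # (H, W, 3) uint8
    mask: np.ndarray         # (H, W) uint8 in {0, 1}
    image_id: str
    source: str
    annotator: int | None = None

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} "
                f"spatial dims differ for {self.image_id}")
        if not np.isin(np.unique(self.mask), (0, 1)).all():
            raise ValueError(f"mask of {self.image_id} is not binary")


def _read_mask(path) -> np.ndarray:
    m = np.asarray(iio.imread(path))
    if m.ndim == 4:  # animated formats (GIF) come back with a frame axis
        m = m[0]
    if m.ndim == 3:
        m = m[..., 0]
    return (m > 0).astype(np.uint8)


def _read_image(path) -> np.ndarray:
    img = np.asarray(iio.imread(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img[..., :3].astype(np.uint8)


def _find_mask(mask_dir: Path, stem_key: str, image_path: Path) -> Path:
    cands = [p for p in sorted(mask_dir.iterdir())
             if p.suffix.lower() in (".gif", ".png", ".tif", ".tiff")
             and p.name.startswith(stem_key)]
    if not cands:
        raise FileNotFoundError(
            f"no mask for image {image_path.name} under {mask_dir}")
    return cands[0]


def _list_images(d: Path):
    if not d.is_dir():
        raise FileNotFoundError(f"expected image directory {d}")
    files = [p for p in sorted(d.iterdir()) if p.suffix in _IMG_EXT
             or p.suffix.lower() in _IMG_EXT]
    if not files:
        raise FileNotFoundError(f"no images found under {d}")
    return files


def _load_drive(root: Path, split: str, annotator: int):
    sub = root / ("training" if split == "train" else "test")
    mask_dir = sub / {1: "1st_manual", 2: "2nd_manual"}[annotator]
    samples = []
    for img_path in _list_images(sub / "images"):
        key = img_path.name.split("_")[0]
        mask_path = _find_mask(mask_dir, key, img_path)
        samples.append(FundusSample(_read_image(img_path), _read_mask(mask_path),
                                    image_id=img_path.stem, source="drive",
                                    annotator=annotator))
    return samples


def _load_hrf(root: Path, split: str, n_train=26):
    # healthy + diabetic-retinopathy images only; sorted order, first 26 train
    imgs = [p for p in _list_images(root / "images")
            if p.stem.split("_")[-1].lower() in ("h", "dr")]
    if not imgs:
        raise FileNotFoundError(f"no healthy/DR images under {root / 'images'}")
    chosen = imgs[:n_train] if split == "train" else imgs[n_train:]
    samples = []
    for img_path in chosen:
        mask_path = _find_mask(root / "manual1", img_path.stem, img_path)
        samples.append(FundusSample(_read_image(img_path), _read_mask(mask_path),
                                    image_id=img_path.stem, source="hrf"))
    return samples


def _load_chasedb(root: Path, split: str, annotator: int, n_train=21):
    imgs = [p for p in _list_images(root)
            if p.suffix.lower() in (".jpg", ".jpeg") and "HO" not in p.stem]
    chosen = imgs[:n_train] if split == "train" else imgs[n_train:]
    suffix = {1: "_1stHO", 2: "_2ndHO"}[annotator]
    samples = []
    for img_path in chosen:
        mask_path = _find_mask(root, img_path.stem + suffix, img_path)
        samples.append(FundusSample(_read_image(img_path), _read_mask(mask_path),
                                    image_id=img_path.stem, source="chasedb",
                                    annotator=annotator))
    return samples


def _load_synthetic(root: Path, split: str):
    manifest = root / "manifest.csv"
    samples = []
    if manifest.exists():
        with open(manifest) as fh:
            rows = [r for r in csv.DictReader(fh)
                    if r.get("split", "train") == split]
        if not rows:
            raise FileNotFoundError(f"manifest has no rows for split {split!r}")
        for r in rows:
            samples.append(FundusSample(_read_image(root / r["image_path"]),
                                        _read_mask(root / r["mask_path"]),
                                        image_id=r["image_id"], source="synthetic"))
        return samples
    for img_path in _list_images(root / "images"):
        mask_path = _find_mask(root / "masks", img_path.stem, img_path)
        samples.append(FundusSample(_read_image(img_path), _read_mask(mask_path),
                                    image_id=img_path.stem, source="synthetic"))
    return samples


def load_dataset(root, layout, split="train", annotator=1):
    """Load a dataset directory in one of the known layouts.

    Returns samples in deterministic order (sorted by image id).  Split sizes
    follow the published protocols when the full datasets are present:
    DRIVE 20/20, HRF 26/4 (healthy + DR only), CHASE_DB1 21/7.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    if split not in ("train", "test"):
        raise ValueError("split must be 'train' or 'test'")
    loaders = {"drive": lambda: _load_drive(root, split, annotator),
               "hrf": lambda: _load_hrf(root, split),
               "chasedb": lambda: _load_chasedb(root, split, annotator),
               "synthetic": lambda: _load_synthetic(root, split)}
    if layout not in loaders:
        raise ValueError(f"unknown layout {layout!r}; choose from {sorted(loaders)}")
    samples = loaders[layout]()
    samples.sort(key=lambda s: s.image_id)
    return samples


def preprocess(sample: FundusSample, size=576):
    """Resize and normalize one sample for inference.

    The image is resized to ``size`` x ``size`` with bilinear interpolation,
    scaled to [0, 1] and channel-normalized with the ImageNet mean/std; the
    mask is resized with nearest-neighbour interpolation so it stays binary.
    Returns (image (3, size, size) float32, mask (size, size) uint8).
    """
    img = sample.image.astype(np.float32) / 255.0
    if img.shape[:2] != (size, size):
        img = resize(img, (size, size), order=1, anti_aliasing=False,
                     preserve_range=True).astype(np.float32)
    img = (img - IMAGENET_MEAN) / IMAGENET_STD
    mask = sample.mask
    if mask.shape != (size, size):
        mask = resize(mask, (size, size), order=0, anti_aliasing=False,
                      preserve_range=True).astype(np.uint8)
    return np.ascontiguousarray(img.transpose(2, 0, 1)), mask


# -- synthetic fundus ------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Parameters of the synthetic fundus generator."""

    seed: int = 0
    size: int = 128
    n_trees: int = 4
    branch_depth: int = 4
    root_width: float = 3.0
    width_decay: float = 0.8
    vessel_intensity: int = 60
    background_intensity: int = 185
    noise_sd: float = 8.0
    fov_radius_frac: float = 0.95

    def __post_init__(self):
        if not 0 < self.width_decay < 1:
            raise ValueError("width_decay must lie in (0, 1)")
        if not 0 < self.fov_radius_frac <= 1:
            raise ValueError("fov_radius_frac must lie in (0, 1]")
        if self.size < 16:
            raise ValueError("size must be at least 16")


def _draw_branch(mask, rng, p, direction, width, depth, length, size):
    n_steps = max(int(length), 2)
    step = 1.0
    for _ in range(n_steps):
        direction += rng.normal(0.0, 0.12)
        p = p + step * np.array([np.cos(direction), np.sin(direction)])
        if not (-width <= p[0] < size + width and -width <= p[1] < size + width):
            break
        rr, cc = disk((p[0], p[1]), max(width / 2.0, 0.7), shape=mask.shape)
        mask[rr, cc] = True
    if depth > 1:
        spread = rng.uniform(0.35, 0.75)
        for sign in (-1.0, 1.0):
            _draw_branch(mask, rng, p, direction + sign * spread,
                         width * rng.uniform(0.9, 1.0), depth - 1,
                         length * 0.8, size)


def generate_synthetic_fundus(config: SyntheticConfig) -> FundusSample:
    """Draw one synthetic fundus photograph and its exact vessel mask.

    Deterministic for a fixed seed.  A circular field of view (FOV) is placed
    on a dark border; inside it, a shaded and textured background carries
    ``n_trees`` recursive branching curves rendered at ``vessel_intensity``.
    The mask is exactly the set of rendered vessel pixels inside the FOV.
    """
    rng = np.random.default_rng(config.seed)
    S = config.size
    yy, xx = np.mgrid[0:S, 0:S].astype(np.float32)
    center = (S - 1) / 2.0
    r = np.hypot(yy - center, xx - center)
    fov = r <= config.fov_radius_frac * S / 2.0

    mask = np.zeros((S, S), dtype=bool)
    # vessels radiate from an optic-disc-like point off centre
    disc_angle = rng.uniform(0, 2 * np.pi)
    disc = np.array([center + 0.45 * center * np.sin(disc_angle),
                     center + 0.45 * center * np.cos(disc_angle)])
    for t in range(config.n_trees):
        angle = rng.uniform(0, 2 * np.pi)
        width = config.root_width * rng.uniform(0.8, 1.2)
        _draw_branch(mask, rng, disc.copy(), angle, width,
                     config.branch_depth, length=0.35 * S, size=S)
    mask &= fov

    shading = 1.0 - 0.3 * (r / (S / 2.0)) ** 2
    texture = gaussian_filter(rng.normal(0.0, 1.0, (S, S)), sigma=S / 16.0) * 18.0
    base = config.background_intensity * shading + texture
    noise = rng.normal(0.0, config.noise_sd, (S, S))
    channel_scale = np.array([1.0, 0.62, 0.40])
    img = base[..., None] * channel_scale[None, None, :]
    img[mask] = config.vessel_intensity * channel_scale
    img += noise[..., None]
    img[~fov] = rng.uniform(0, 4)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return FundusSample(image=img, mask=mask.astype(np.uint8),
                        image_id=f"synthetic_{config.seed:06d}",
                        source="synthetic")


def vessel_fraction(sample: FundusSample, fov_radius_frac=0.95) -> float:
    """Fraction of FOV pixels labelled vessel."""
    S = sample.mask.shape[0]
    yy, xx = np.mgrid[0:S, 0:S].astype(np.float32)
    center = (S - 1) / 2.0
    fov = np.hypot(yy - center, xx - center) <= fov_radius_frac * S / 2.0
    return float(sample.mask[fov].sum() / fov.sum())


def synthesize_dataset(n, base_seed=0, **config_kwargs):
    """Generate ``n`` samples with seeds base_seed .. base_seed+n-1."""
    return [generate_synthetic_fundus(SyntheticConfig(seed=base_seed + i, **config_kwargs))
            for i in range(n)]


def write_synthetic_dataset(root, samples, split="train"):
    """Write samples as paired PNGs plus a manifest CSV (synthetic layout)."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    manifest = root / "manifest.csv"
    new_rows = []
    for s in samples:
        img_rel = f"images/{s.image_id}.png"
        mask_rel = f"masks/{s.image_id}.png"
        iio.imwrite(root / img_rel, s.image)
        iio.imwrite(root / mask_rel, (s.mask * 255).astype(np.uint8))
        new_rows.append({"image_id": s.image_id, "image_path": img_rel,
                         "mask_path": mask_rel, "split": split})
    exists = manifest.exists()
    with open(manifest, "a", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["image_id", "image_path",
                                                "mask_path", "split"])
        if not exists:
            writer.writeheader()
        writer.writerows(new_rows)
    return manifest
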