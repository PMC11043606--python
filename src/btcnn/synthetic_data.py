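"""Seeded phantom MRI generator in the directory-per-class layout.

Each phantom is a bright skull-like elliptical ring with brain tissue
inside, on a near-black background, plus class-dependent lesion
geometry:

* ``notumor`` -- no lesion;
* ``glioma`` -- an irregular blob (randomised radial harmonics) anywhere
  in the brain;
* ``meningioma`` -- an ellipse attached to the inner skull rim;
* ``pituitary`` -- a small disk at the central base of the brain.

Classes are separable by lesion shape and position rather than by mean
intensity, so a classifier has to learn spatial features; no anatomical
realism is claimed.  Background stays well below the preprocessing
threshold of 45 so the skull drives the crop box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .preprocess import CLASSES

__all__ = ["PhantomConfig", "generate_dataset", "separability_check"]


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters; defaults give 256x256 pre-crop phantoms."""

    n_per_class: int = 30
    image_size: tuple[int, int] = (256, 256)
    classes: tuple[str, ...] = CLASSES
    noise_sd: float = 4.0
    background_level: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomConfig":
        doc = yaml.safe_load(text) or {}
        if "image_size" in doc:
            doc["image_size"] = tuple(doc["image_size"])
        if "classes" in doc:
            doc["classes"] = tuple(doc["classes"])
        return cls(**doc)


def _ellipse_mask(h, w, cy, cx, ry, rx, angle=0.0):
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    if angle:
        c, s = np.cos(angle), np.sin(angle)
        dy, dx = c * dy - s * dx, s * dy + c * dx
    return (dy / ry) ** 2 + (dx / rx) ** 2 <= 1.0


def _blob_mask(h, w, cy, cx, r0, rng):
    """Irregular blob: radius modulated by random low-order harmonics."""
    amps = rng.uniform(0.08, 0.22, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    r = r0 * (
        1.0
        + sum(a * np.sin((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amps, phases)))
    )
    return dy**2 + dx**2 <= r**2


def _render_phantom(cls: str, size, rng, noise_sd, background):
    h, w = size
    img = np.full((h, w), background, dtype=float)
    cy, cx = h / 2 + rng.uniform(-4, 4), w / 2 + rng.uniform(-4, 4)
    ry = h * rng.uniform(0.37, 0.42)
    rx = w * rng.uniform(0.33, 0.38)
    thickness = rng.uniform(5, 8)

    outer = _ellipse_mask(h, w, cy, cx, ry, rx)
    inner = _ellipse_mask(h, w, cy, cx, ry - thickness, rx - thickness)
    img[outer & ~inner] = rng.uniform(195, 215)  # skull ring
    # brain tissue with gentle low-frequency texture
    yy, xx = np.mgrid[0:h, 0:w]
    texture = 8 * np.sin(2 * np.pi * yy / h * rng.uniform(1, 3) + rng.uniform(0, 6)) * np.cos(
        2 * np.pi * xx / w * rng.uniform(1, 3) + rng.uniform(0, 6)
    )
    img[inner] = 85 + texture[inner]

    params = {"lesion_cy": np.nan, "lesion_cx": np.nan, "lesion_size": np.nan}
    if cls == "glioma":
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.15, 0.45)
        lcy = cy + rad * (ry - thickness) * np.sin(ang)
        lcx = cx + rad * (rx - thickness) * np.cos(ang)
        r0 = min(h, w) * rng.uniform(0.10, 0.15)
        lesion = _blob_mask(h, w, lcy, lcx, r0, rng) & inner
        img[lesion] = rng.uniform(165, 185)
        params = {"lesion_cy": lcy, "lesion_cx": lcx, "lesion_size": r0}
    elif cls == "meningioma":
        ang = rng.uniform(0, 2 * np.pi)
        lcy = cy + 0.82 * (ry - thickness) * np.sin(ang)
        lcx = cx + 0.82 * (rx - thickness) * np.cos(ang)
        a = h * rng.uniform(0.06, 0.09)
        b = w * rng.uniform(0.09, 0.13)
        lesion = _ellipse_mask(h, w, lcy, lcx, a, b, angle=ang) & inner
        img[lesion] = rng.uniform(205, 225)
        params = {"lesion_cy": lcy, "lesion_cx": lcx, "lesion_size": (a + b) / 2}
    elif cls == "pituitary":
        lcy = cy + 0.55 * (ry - thickness)
        lcx = cx + rng.uniform(-0.06, 0.06) * rx
        r0 = min(h, w) * rng.uniform(0.045, 0.065)
        lesion = _ellipse_mask(h, w, lcy, lcx, r0, r0) & inner
        img[lesion] = rng.uniform(200, 220)
        params = {"lesion_cy": lcy, "lesion_cx": lcx, "lesion_size": r0}
    elif cls != "notumor":
        raise ValueError(f"unknown class {cls!r}")

    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), params


def generate_dataset(config: PhantomConfig, out_dir) -> pd.DataFrame:
    """Write ``n_per_class`` PNGs per class directory; returns the manifest.

    Byte-identical across runs with the same config (one generator seeded
    by ``config.seed`` drives every draw, and files are written in a
    fixed order).  The manifest (also written as ``manifest.csv``) lists
    path, class, class index and lesion parameters.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}") from exc
    rng = np.random.default_rng(config.seed)
    rows = []
    for ci, cls in enumerate(config.classes):
        class_dir = out / cls
        class_dir.mkdir(exist_ok=True)
        for i in range(config.n_per_class):
            img, params = _render_phantom(
                cls, config.image_size, rng, config.noise_sd, config.background_level
            )
            path = class_dir / f"{cls}_{i:04d}.png"
            Image.fromarray(img, mode="L").save(path)
            rows.append({"path": str(path), "class": cls, "class_index": ci, **params})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def _downsample(images: np.ndarray, side: int = 16) -> np.ndarray:
    n, h, w = images.shape[:3]
    bh, bw = h // side, w // side
    cropped = images[:, : side * bh, : side * bw]
    return cropped.reshape(n, side, bh, side, bw).mean(axis=(2, 4)).reshape(n, -1)


def separability_check(images: np.ndarray, labels: np.ndarray, side: int = 16) -> float:
    """Leave-one-out nearest-centroid accuracy on downsampled images.

    Certifies that a generated set is learnable: well above the 0.25
    chance level for the default geometries, near chance when lesions are
    disabled.  Returns NaN (with a warning) when any class has a single
    example, since leave-one-out centroids are undefined there.
    """
    y = np.asarray(labels)
    if y.ndim == 2:
        y = y.argmax(axis=1)
    X = _downsample(np.asarray(images, dtype=float), side)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        warnings.warn("separability check skipped: a class has fewer than 2 examples")
        return float("nan")
    sums = np.stack([X[y == c].sum(axis=0) for c in classes])
    correct = 0
    for i in range(len(X)):
        cent = sums / counts[:, None]
        own = np.where(classes == y[i])[0][0]
        cent[own] = (sums[own] - X[i]) / (counts[own] - 1)
        d = ((cent - X[i]) ** 2).sum(axis=1)
        correct += int(classes[d.argmin()] == y[i])
    return correct / len(X)
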