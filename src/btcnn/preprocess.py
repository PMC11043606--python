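"""Seven-step MRI slice preparation chain.

Raw class-foldered PNG/JPEG slices are turned into normalised 200x200
grayscale tensors with one-hot labels:

1. reduce to one channel (luminance weights 0.299/0.587/0.114),
2. Gaussian blur (3x3 window),
3. CLAHE contrast enhancement (clip limit 2, 8x8 tiles),
4. binary threshold at 45 plus erosion/dilation to clean the mask,
5. crop to the bounding box of the largest foreground component,
6. bilinear resize to 200x200,
7. one-hot encode the class from the directory name
   (0=glioma, 1=meningioma, 2=notumor, 3=pituitary).

The binary mask only *locates* the crop box; the cropped pixels come from
the CLAHE-enhanced image.  Intensities are scaled to [0, 1] at the end.
CLAHE follows the usual clip-limited formulation: per-tile histograms are
clipped at ``clip x mean bin height``, the excess is redistributed
uniformly, and neighbouring tile mappings are blended bilinearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CLASSES",
    "PreprocessConfig",
    "LabeledExample",
    "to_grayscale",
    "gaussian_kernel",
    "gaussian_blur",
    "clahe",
    "binary_mask",
    "morphology_clean",
    "find_crop_box",
    "resize",
    "one_hot",
    "preprocess_array",
    "preprocess_image",
    "load_dataset",
    "MRIPreprocessor",
]

CLASSES = ("glioma", "meningioma", "notumor", "pituitary")


@dataclass(frozen=True)
class PreprocessConfig:
    """All pipeline constants.

    ``blur_sigma=0`` derives sigma from the window size with the usual
    rule ``0.3*((k-1)/2 - 1) + 0.8`` (0.8 for a 3x3 window).
    """

    blur_window: tuple[int, int] = (3, 3)
    blur_sigma: float = 0.0
    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    threshold: int = 45
    morph_window: tuple[int, int] = (3, 3)
    erode_iters: int = 2
    dilate_iters: int = 2
    target_size: tuple[int, int] = (200, 200)

    def __post_init__(self):
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold must be in [0, 255]")
        if any(w < 1 for w in self.blur_window + self.morph_window):
            raise ValueError("window sizes must be >= 1")
        if any(t < 1 for t in self.target_size):
            raise ValueError("target size must be positive")

    def effective_sigma(self) -> float:
        if self.blur_sigma > 0:
            return self.blur_sigma
        k = self.blur_window[0]
        return 0.3 * ((k - 1) / 2 - 1) + 0.8


@dataclass(frozen=True)
class LabeledExample:
    image: np.ndarray  # (target_h, target_w) float in [0, 1]
    label: np.ndarray  # one-hot over the 4 classes
    source_path: str


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse a 1- or 3-channel image to luminance, range [0, 255]."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 1:
        return img[:, :, 0]
    if img.ndim == 3 and img.shape[2] == 3:
        return img @ np.array([0.299, 0.587, 0.114])
    raise ValueError(f"expected 1 or 3 channels, got shape {img.shape}")


def gaussian_kernel(sigma: float, window: tuple[int, int] = (3, 3)) -> np.ndarray:
    """Normalised 2-D Gaussian, G(x, y) = exp(-(x^2+y^2)/(2 sigma^2)) / Z."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    kh, kw = window
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("window sides must be odd")
    ys = np.arange(kh) - kh // 2
    xs = np.arange(kw) - kw // 2
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    k = np.exp(-(xx**2 + yy**2) / (2 * sigma**2)) / (2 * math.pi * sigma**2)
    return k / k.sum()


def gaussian_blur(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """3x3 Gaussian smoothing with reflective borders; size preserved."""
    config = config or PreprocessConfig()
    kernel = gaussian_kernel(config.effective_sigma(), config.blur_window)
    return ndimage.convolve(np.asarray(image, dtype=float), kernel, mode="reflect")


def clahe(
    image: np.ndarray,
    clip: float = 2.0,
    tiles: tuple[int, int] = (8, 8),
    n_bins: int = 256,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on a [0, 255] image.

    The image is split into ``tiles`` regions; each tile's histogram is
    clipped at ``clip`` times the mean bin height and the clipped excess
    redistributed uniformly before forming the equalising mapping.  Pixel
    values are remapped by bilinear interpolation between the four
    surrounding tile mappings, which removes tile-boundary artefacts.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if clip <= 0:
        raise ValueError("clip limit must be positive")
    ty, tx = tiles
    if ty < 1 or tx < 1:
        raise ValueError("tile counts must be >= 1")

    levels = np.clip(img, 0, 255).astype(np.int64)
    levels = np.minimum(levels * n_bins // 256, n_bins - 1)
    h, w = img.shape
    # pad so the grid divides evenly (reflect, as OpenCV does)
    ph, pw = (-h) % ty, (-w) % tx
    lv = np.pad(levels, ((0, ph), (0, pw)), mode="symmetric")
    hp, wp = lv.shape
    th, tw = hp // ty, wp // tx

    # per-tile clipped histograms -> per-tile mappings to [0, 255]
    tiles_view = lv.reshape(ty, th, tx, tw).transpose(0, 2, 1, 3).reshape(ty, tx, -1)
    maps = np.empty((ty, tx, n_bins))
    tile_pixels = th * tw
    clip_height = max(clip * tile_pixels / n_bins, 1.0)
    for i in range(ty):
        for j in range(tx):
            hist = np.bincount(tiles_view[i, j], minlength=n_bins).astype(float)
            excess = np.maximum(hist - clip_height, 0).sum()
            hist = np.minimum(hist, clip_height) + excess / n_bins
            cdf = hist.cumsum()
            maps[i, j] = cdf * (255.0 / tile_pixels)

    # bilinear blend of the four surrounding tile mappings
    centers_y = (np.arange(ty) + 0.5) * th
    centers_x = (np.arange(tx) + 0.5) * tw
    yy = np.arange(hp)[:, None]
    xx = np.arange(wp)[None, :]
    fy = np.clip((yy - centers_y[0]) / th, 0, ty - 1)
    fx = np.clip((xx - centers_x[0]) / tw, 0, tx - 1)
    y0 = np.floor(fy).astype(int)
    x0 = np.floor(fx).astype(int)
    y1 = np.minimum(y0 + 1, ty - 1)
    x1 = np.minimum(x0 + 1, tx - 1)
    wy = fy - y0
    wx = fx - x0

    y0b, y1b = np.broadcast_to(y0, (hp, wp)), np.broadcast_to(y1, (hp, wp))
    x0b, x1b = np.broadcast_to(x0, (hp, wp)), np.broadcast_to(x1, (hp, wp))
    out = (
        (1 - wy) * (1 - wx) * maps[y0b, x0b, lv]
        + (1 - wy) * wx * maps[y0b, x1b, lv]
        + wy * (1 - wx) * maps[y1b, x0b, lv]
        + wy * wx * maps[y1b, x1b, lv]
    )
    return np.clip(out[:h, :w], 0, 255)


def binary_mask(image: np.ndarray, threshold: int = 45) -> np.ndarray:
    """Foreground where intensity >= threshold (strictly below -> 0)."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    return np.asarray(image) >= threshold


def morphology_clean(mask: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Erosions then dilations with a rectangular structuring element."""
    config = config or PreprocessConfig()
    m = np.asarray(mask, dtype=bool)
    selem = np.ones(config.morph_window, dtype=bool)
    if config.erode_iters > 0:
        m = ndimage.binary_erosion(m, selem, iterations=config.erode_iters)
    if config.dilate_iters > 0:
        m = ndimage.binary_dilation(m, selem, iterations=config.dilate_iters)
    return m


def find_crop_box(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Bounding box (row_min, col_min, row_max, col_max), inclusive, of the
    largest connected foreground component; the full frame if the mask is
    empty."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return (0, 0, m.shape[0] - 1, m.shape[1] - 1)
    labels, n = ndimage.label(m)
    if n > 1:
        sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
        largest = int(sizes.argmax()) + 1
    else:
        largest = 1
    rows, cols = np.nonzero(labels == largest)
    return (int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max()))


def resize(image: np.ndarray, target: tuple[int, int] = (200, 200)) -> np.ndarray:
    """Bilinear resize to exactly ``target`` (height, width)."""
    img = np.asarray(image, dtype=float)
    if img.size == 0 or img.ndim != 2:
        raise ValueError("cannot resize a degenerate image")
    if img.shape == tuple(target):
        return img.copy()
    return _sk_resize(
        img, target, order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )


def one_hot(class_index: int, n_classes: int = len(CLASSES)) -> np.ndarray:
    if not 0 <= class_index < n_classes:
        raise ValueError(f"class index {class_index} outside [0, {n_classes - 1}]")
    v = np.zeros(n_classes)
    v[class_index] = 1.0
    return v


def preprocess_array(
    image: np.ndarray, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Run steps 1-6 on an in-memory image; returns ([0,1] tensor, crop box)."""
    config = config or PreprocessConfig()
    gray = to_grayscale(image)
    blurred = gaussian_blur(gray, config)
    enhanced = clahe(blurred, config.clahe_clip, config.clahe_tiles)
    mask = morphology_clean(binary_mask(enhanced, config.threshold), config)
    r0, c0, r1, c1 = find_crop_box(mask)
    cropped = enhanced[r0 : r1 + 1, c0 : c1 + 1]
    out = resize(cropped, config.target_size) / 255.0
    return np.clip(out, 0.0, 1.0), (r0, c0, r1, c1)


def _class_index_from_path(path: Path) -> int:
    name = path.parent.name.lower()
    if name not in CLASSES:
        raise ValueError(
            f"directory {name!r} of {path} is not one of the classes {CLASSES}"
        )
    return CLASSES.index(name)


def preprocess_image(path, config: PreprocessConfig | None = None) -> LabeledExample:
    """Full chain on one file inside a class-named directory."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB") if im.mode not in ("L", "I") else im)
    except OSError as exc:
        raise OSError(f"cannot read image file {path}") from exc
    idx = _class_index_from_path(path)
    image, _ = preprocess_array(arr, config)
    return LabeledExample(image=image, label=one_hot(idx), source_path=str(path))


def load_dataset(
    root, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Preprocess a directory-per-class tree.

    Returns ``(images, labels, manifest)``: image stack ``(N, H, W)`` in
    [0, 1], one-hot labels ``(N, 4)``, and a manifest with path, class
    index and crop box per example.  Files are visited in sorted order so
    the result is deterministic.
    """
    root = Path(root)
    config = config or PreprocessConfig()
    if not root.is_dir():
        raise OSError(f"dataset directory {root} does not exist")
    images, labels, rows = [], [], []
    for cls in CLASSES:
        class_dir = root / cls
        if not class_dir.is_dir():
            continue
        for path in sorted(class_dir.iterdir()):
            if path.suffix.lower() not in {".png", ".jpg", ".jpeg"}:
                continue
            with Image.open(path) as im:
                arr = np.asarray(im.convert("RGB") if im.mode not in ("L", "I") else im)
            img, box = preprocess_array(arr, config)
            images.append(img)
            labels.append(one_hot(CLASSES.index(cls)))
            rows.append(
                {
                    "path": str(path),
                    "class": cls,
                    "class_index": CLASSES.index(cls),
                    "row_min": box[0],
                    "col_min": box[1],
                    "row_max": box[2],
                    "col_max": box[3],
                }
            )
    if not images:
        raise OSError(f"no class images found under {root}")
    return np.stack(images), np.stack(labels), pd.DataFrame(rows)


class MRIPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer over in-memory image stacks.

    ``transform`` maps ``(n, H, W[, C])`` raw images to ``(n, th, tw)``
    normalised tensors; ``fit`` is a no-op kept for pipeline compatibility.
    """

    def __init__(self, config: PreprocessConfig | None = None) -> None:
        self.config = config

    def fit(self, X, y=None) -> "MRIPreprocessor":
        self.n_features_in_ = int(np.prod(np.asarray(X[0]).shape))
        return self

    def transform(self, X) -> np.ndarray:
        config = self.config or PreprocessConfig()
        return np.stack([preprocess_array(x, config)[0] for x in X])
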