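"""Paired image–mask datasets: containers, PNG/TIFF I/O, resizing, binarization.

Conventions used throughout the package:

* a *grayscale image* is a 2-D ``float32`` array with values in [0, 1];
* a *binary mask* is a 2-D ``uint8`` array with values in {0, 1};
* on disk both are 8-bit single-channel rasters, images via ``round(v*255)``
  and masks as {0, 255}; masks are re-binarized on load at 128/255 so that
  antialiased third-party masks still round-trip to {0, 1};
* thresholding is always "``>= threshold`` is foreground".
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "ImagePair",
    "DatasetLayout",
    "PairingError",
    "binarize",
    "as_gray_image",
    "as_binary_mask",
    "load_pairs",
    "save_pairs",
    "resize_pair",
]

_READ_SUFFIXES = (".png", ".tif", ".tiff")


class PairingError(ValueError):
    """An image file without a same-stem mask file, or vice versa."""


def as_gray_image(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce to the in-memory grayscale convention."""
    a = np.asarray(arr, dtype=np.float32)
    if a.ndim != 2:
        raise ValueError(f"grayscale image must be 2-D, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("grayscale image contains non-finite values")
    if a.size and (a.min() < 0.0 or a.max() > 1.0):
        raise ValueError("grayscale image values must lie in [0, 1]")
    return a


def as_binary_mask(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce to the in-memory {0,1} mask convention."""
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {a.shape}")
    u = np.unique(a)
    if not np.all(np.isin(u, (0, 1))):
        raise ValueError(f"mask values must be exactly {{0,1}}, found {u}")
    return a.astype(np.uint8)


@dataclass
class ImagePair:
    """An aligned (image, mask) pair — the training atom of every segmenter.

    ``clean_mask`` optionally retains the uncorrupted reference when the
    working ``mask`` has been deliberately perturbed (annotation-error
    experiments); it is ``None`` for pristine pairs.
    """

    image: np.ndarray
    mask: np.ndarray
    pair_id: str
    provenance: str = "synthetic"  # "synthetic" | "loaded"
    clean_mask: np.ndarray | None = None

    def __post_init__(self):
        self.image = as_gray_image(self.image)
        self.mask = as_binary_mask(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} differ in shape"
            )
        if self.provenance not in ("synthetic", "loaded"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def reference_mask(self) -> np.ndarray:
        """The mask to evaluate against: the clean one when it exists."""
        return self.mask if self.clean_mask is None else self.clean_mask


@dataclass
class DatasetLayout:
    """Directory layout ``root/{images,masks}/<stem>.png`` paired by stem."""

    root: pathlib.Path
    images_dir: str = "images"
    masks_dir: str = "masks"

    def __post_init__(self):
        self.root = pathlib.Path(self.root)

    @property
    def images_path(self) -> pathlib.Path:
        return self.root / self.images_dir

    @property
    def masks_path(self) -> pathlib.Path:
        return self.root / self.masks_dir


def binarize(image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a grayscale image into a mask; ``>= threshold`` is foreground."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    img = as_gray_image(image)
    return (img >= threshold).astype(np.uint8)


def _read_gray(path: pathlib.Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        # tolerate single-channel files saved with an explicit channel axis
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"{path.name}: expected grayscale, got {arr.shape[2]} channels")
    return np.asarray(arr)


def _stems(directory: pathlib.Path) -> dict[str, pathlib.Path]:
    out: dict[str, pathlib.Path] = {}
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in _READ_SUFFIXES:
            out[p.stem] = p
    return out


def load_pairs(layout: DatasetLayout) -> list[ImagePair]:
    """Load every stem-matched (image, mask) pair under the layout, sorted by id."""
    images = _stems(layout.images_path)
    masks = _stems(layout.masks_path)
    orphans = sorted(set(images) ^ set(masks))
    if orphans:
        raise PairingError(f"unpaired stems (missing image or mask): {orphans}")
    pairs = []
    for stem in sorted(images):
        img = _read_gray(images[stem]).astype(np.float32) / 255.0
        raw = _read_gray(masks[stem]).astype(np.float32) / 255.0
        pairs.append(
            ImagePair(image=img, mask=binarize(raw, 128.0 / 255.0), pair_id=stem, provenance="loaded")
        )
    return pairs


def save_pairs(pairs: list[ImagePair], layout: DatasetLayout) -> int:
    """Write pairs as 8-bit PNGs under the layout; returns the count written."""
    layout.images_path.mkdir(parents=True, exist_ok=True)
    layout.masks_path.mkdir(parents=True, exist_ok=True)
    for pair in pairs:
        img8 = np.round(pair.image * 255.0).astype(np.uint8)
        msk8 = (pair.mask * 255).astype(np.uint8)
        iio.imwrite(layout.images_path / f"{pair.pair_id}.png", img8)
        iio.imwrite(layout.masks_path / f"{pair.pair_id}.png", msk8)
    return len(pairs)


def _check_pow2(size: int) -> None:
    if size < 32 or (size & (size - 1)) != 0:
        raise ValueError(
            f"target size must be a power of two >= 32 (network depth requirement), got {size}"
        )


def resize_pair(pair: ImagePair, size: int) -> ImagePair:
    """Resize to size x size: bilinear for the image, nearest for the mask."""
    _check_pow2(size)
    if pair.image.shape == (size, size):
        return pair
    img = _sk_resize(pair.image, (size, size), order=1, anti_aliasing=False,
                     preserve_range=True).astype(np.float32)
    msk = _sk_resize(pair.mask, (size, size), order=0, anti_aliasing=False,
                     preserve_range=True)
    clean = pair.clean_mask
    if clean is not None:
        clean = as_binary_mask(_sk_resize(clean, (size, size), order=0,
                                          anti_aliasing=False, preserve_range=True))
    return ImagePair(
        image=np.clip(img, 0.0, 1.0),
        mask=as_binary_mask(msk),
        pair_id=pair.pair_id,
        provenance=pair.provenance,
        clean_mask=clean,
    )
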