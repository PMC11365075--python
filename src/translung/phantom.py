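"""Synthetic thoracic-slice phantoms with exact ground-truth lung masks.

Each phantom is a 2-D grayscale scene mimicking a lung-window CT slice: a
dark background, a bright elliptical torso, and two darker lung fields
rendered as independently jittered, slightly rotated ellipses, optionally
decorated with bright intralung nodules and vessel-like line clutter, then
Gaussian-blurred and corrupted with additive noise. The ground-truth mask
is the pre-noise lung geometry.

Calibration: the two base lung semi-axes are solved analytically from
``lung_area_fraction_target`` (default 0.2543, the mean lung-area fraction
of the real dataset the package emulates) before multiplicative axis jitter
is applied. The jitter factors are independent with unit mean, so the
*expected* lung-area fraction equals the target while individual draws vary
around it, matching a dataset-level average rather than a per-image
constraint.

An annotation-error mode (`corrupt_labels`) emulates expert mistakes seen
in real manual segmentations: masks covering only one lateral half of the
lungs, incompletely removed background, or eroded/dilated boundaries. The
clean mask is retained on every corrupted pair so experiments can always
evaluate against truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .pairs_io import ImagePair

__all__ = [
    "PhantomParams",
    "CorruptionSpec",
    "generate_phantom",
    "generate_dataset",
    "corrupt_labels",
]

# Height/width ratio of the base lung ellipses before jitter. Lungs are
# taller than wide; the value also keeps default-sized lungs inside the
# torso after maximal jitter and rotation.
_LUNG_ASPECT = 2.2
_LUNG_CENTER_OFFSET = 0.17  # lateral lung-center offset, fraction of image side
_TORSO_SEMI_AXES = (0.46, 0.40)  # (x, y), fraction of image side


@dataclass
class PhantomParams:
    """Rendering parameters; all intensities are abstract values in [0, 1]."""

    image_size: int = 256
    torso_intensity_range: tuple[float, float] = (0.55, 0.85)
    lung_intensity_range: tuple[float, float] = (0.08, 0.32)
    background_intensity: float = 0.05
    lung_area_fraction_target: float = 0.2543
    lung_eccentricity_range: tuple[float, float] = (0.88, 1.12)
    nodule_count_range: tuple[int, int] = (0, 3)
    nodule_radius_range: tuple[float, float] = (2.0, 6.0)
    vessel_density: float = 0.5
    noise_sd: float = 0.02
    blur_sigma: float = 0.7

    def validate(self) -> None:
        s = self.image_size
        if s < 32 or (s & (s - 1)) != 0:
            raise ValueError("image_size must be a power of two >= 32")
        for name in ("torso_intensity_range", "lung_intensity_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 <= low <= high <= 1")
        if not 0.0 <= self.background_intensity <= 1.0:
            raise ValueError("background_intensity must lie in [0, 1]")
        if self.lung_intensity_range[1] >= self.torso_intensity_range[0]:
            raise ValueError(
                "lung_intensity_range must lie entirely below torso_intensity_range "
                "(lungs render dark on bright tissue)"
            )
        if not 0.0 < self.lung_area_fraction_target < 1.0:
            raise ValueError("lung_area_fraction_target must lie in (0, 1)")
        lo, hi = self.lung_eccentricity_range
        if not (0.0 < lo <= hi):
            raise ValueError("lung_eccentricity_range must satisfy 0 < low <= high")
        nlo, nhi = self.nodule_count_range
        if not (0 <= nlo <= nhi):
            raise ValueError("nodule_count_range must satisfy 0 <= low <= high")
        rlo, rhi = self.nodule_radius_range
        if not (0.0 < rlo <= rhi):
            raise ValueError("nodule_radius_range must satisfy 0 < low <= high")
        if self.vessel_density < 0.0:
            raise ValueError("vessel_density must be >= 0")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be >= 0")
        if self.blur_sigma < 0.0:
            raise ValueError("blur_sigma must be >= 0")


@dataclass
class CorruptionSpec:
    """Annotation-error model applied to a dataset's masks."""

    mode: str = "half_lung"  # half_lung | residual_background | dilate_erode
    fraction_corrupted: float = 0.2
    magnitude: float = 4.0

    def validate(self) -> None:
        if self.mode not in ("half_lung", "residual_background", "dilate_erode"):
            raise ValueError(f"unknown corruption mode {self.mode!r}")
        if not 0.0 <= self.fraction_corrupted <= 1.0:
            raise ValueError("fraction_corrupted must lie in [0, 1]")
        if self.magnitude < 0.0:
            raise ValueError("magnitude must be >= 0")


def _ellipse_mask(size: int, cx: float, cy: float, ax: float, ay: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    c, s = np.cos(theta), np.sin(theta)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def _base_lung_axes(size: int, fraction: float) -> tuple[float, float]:
    # two ellipses, each of area pi*ax*ay, together covering `fraction` of size^2
    ax = np.sqrt(fraction * size * size / (2.0 * np.pi * _LUNG_ASPECT))
    return ax, _LUNG_ASPECT * ax


def generate_phantom(params: PhantomParams, seed: int) -> ImagePair:
    """Render one phantom; a pure function of (params, seed)."""
    params.validate()
    rng = np.random.default_rng(seed)
    s = params.image_size

    torso_int = rng.uniform(*params.torso_intensity_range)
    lung_int = rng.uniform(*params.lung_intensity_range)

    tj = rng.uniform(0.96, 1.04, size=2)  # mild torso shape variation
    torso = _ellipse_mask(s, 0.5 * s, 0.5 * s,
                          _TORSO_SEMI_AXES[0] * s * tj[0],
                          _TORSO_SEMI_AXES[1] * s * tj[1], 0.0)

    ax0, ay0 = _base_lung_axes(s, params.lung_area_fraction_target)
    lungs = np.zeros((s, s), dtype=bool)
    for side in (-1.0, 1.0):
        jx = rng.uniform(*params.lung_eccentricity_range)
        jy = rng.uniform(*params.lung_eccentricity_range)
        theta = rng.uniform(-np.deg2rad(8.0), np.deg2rad(8.0))
        cx = (0.5 + side * _LUNG_CENTER_OFFSET) * s
        cy = 0.5 * s
        lungs |= _ellipse_mask(s, cx, cy, ax0 * jx, ay0 * jy, theta)
    lungs &= torso  # lungs cannot protrude from the body

    scene = np.full((s, s), params.background_intensity, dtype=np.float64)
    scene[torso] = torso_int
    scene[lungs] = lung_int

    # intralung clutter: bright nodules and vessel-like line segments
    lung_idx = np.argwhere(lungs)
    n_nodules = int(rng.integers(params.nodule_count_range[0],
                                 params.nodule_count_range[1] + 1))
    if len(lung_idx):
        yy, xx = np.mgrid[0:s, 0:s]
        for _ in range(n_nodules):
            cy, cx = lung_idx[rng.integers(len(lung_idx))]
            r = rng.uniform(*params.nodule_radius_range)
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            scene[disk & lungs] = rng.uniform(*params.torso_intensity_range)
        n_vessels = int(rng.poisson(params.vessel_density * 4.0))
        for _ in range(n_vessels):
            p0 = lung_idx[rng.integers(len(lung_idx))]
            p1 = lung_idx[rng.integers(len(lung_idx))]
            n_steps = int(max(abs(p1[0] - p0[0]), abs(p1[1] - p0[1]))) + 1
            ys = np.round(np.linspace(p0[0], p1[0], n_steps)).astype(int)
            xs = np.round(np.linspace(p0[1], p1[1], n_steps)).astype(int)
            keep = lungs[ys, xs]
            scene[ys[keep], xs[keep]] = rng.uniform(*params.torso_intensity_range)

    if params.blur_sigma > 0.0:
        scene = ndimage.gaussian_filter(scene, params.blur_sigma)
    if params.noise_sd > 0.0:
        scene = scene + rng.normal(0.0, params.noise_sd, size=scene.shape)
    scene = np.clip(scene, 0.0, 1.0)

    return ImagePair(
        image=scene.astype(np.float32),
        mask=lungs.astype(np.uint8),
        pair_id=f"phantom_{seed}",
        provenance="synthetic",
    )


def generate_dataset(
    n_train: int = 237,
    n_test: int = 30,
    params: PhantomParams | None = None,
    seed: int = 0,
) -> tuple[list[ImagePair], list[ImagePair]]:
    """Draw independent train/test phantom cohorts with unique, stable ids."""
    if n_train < 0 or n_test < 0:
        raise ValueError("n_train and n_test must be >= 0")
    params = params or PhantomParams()
    params.validate()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_train + n_test)
    # keep the per-pair seeds below 2**31 so they stay plain ints everywhere
    child_seeds = (child_seeds % np.uint32(2**31)).tolist()
    train, test = [], []
    for i in range(n_train):
        p = generate_phantom(params, int(child_seeds[i]))
        p.pair_id = f"train_{i:04d}"
        train.append(p)
    for i in range(n_test):
        p = generate_phantom(params, int(child_seeds[n_train + i]))
        p.pair_id = f"test_{i:04d}"
        test.append(p)
    return train, test


def _corrupt_half_lung(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cols = np.nonzero(mask.any(axis=0))[0]
    if len(cols) == 0:
        return mask.copy()
    centre = int(np.round(mask.nonzero()[1].mean()))
    out = mask.copy()
    if rng.random() < 0.5:
        out[:, :centre] = 0  # keep the right lung only
    else:
        out[:, centre:] = 0
    return out


def _corrupt_residual_background(mask: np.ndarray, image: np.ndarray,
                                 width: int, rng: np.random.Generator) -> np.ndarray:
    # incomplete background removal: a band of spurious foreground hugging
    # the outer torso boundary, located from the image itself
    from .classical import otsu_threshold

    thr, _ = otsu_threshold(image, dark_foreground=True)
    body = image >= thr  # bright torso tissue
    body = ndimage.binary_fill_holes(body)
    ring = body & ~ndimage.binary_erosion(body, iterations=max(1, width))
    out = mask.copy()
    out[ring & (mask == 0)] = 1
    return out


def _corrupt_dilate_erode(mask: np.ndarray, magnitude: int,
                          rng: np.random.Generator) -> np.ndarray:
    it = max(1, magnitude)
    if rng.random() < 0.5:
        return ndimage.binary_dilation(mask, iterations=it).astype(np.uint8)
    return ndimage.binary_erosion(mask, iterations=it).astype(np.uint8)


def corrupt_labels(pairs: list[ImagePair], spec: CorruptionSpec, seed: int) -> list[ImagePair]:
    """Replace the mask (never the image) of a random subset of pairs.

    Corrupted pairs carry their original mask in ``clean_mask`` so that
    evaluation against truth remains possible.
    """
    if not pairs:
        raise ValueError("pairs must be nonempty")
    spec.validate()
    rng = np.random.default_rng(seed)
    n_corrupt = int(round(spec.fraction_corrupted * len(pairs)))
    chosen = set(rng.choice(len(pairs), size=n_corrupt, replace=False).tolist())
    out: list[ImagePair] = []
    for i, pair in enumerate(pairs):
        if i not in chosen:
            out.append(pair)
            continue
        if spec.mode == "half_lung":
            bad = _corrupt_half_lung(pair.mask, rng)
        elif spec.mode == "residual_background":
            bad = _corrupt_residual_background(pair.mask, pair.image,
                                               int(spec.magnitude), rng)
        else:
            bad = _corrupt_dilate_erode(pair.mask, int(spec.magnitude), rng)
        out.append(ImagePair(image=pair.image, mask=bad, pair_id=pair.pair_id,
                             provenance=pair.provenance, clean_mask=pair.mask.copy()))
    return out
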