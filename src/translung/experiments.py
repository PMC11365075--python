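"""Shared experiment harness used by the command-line interface and tests.

Bundles the repeated patterns of the package's studies: train a method on a
phantom (or loaded) cohort, segment a held-out cohort, score it, and build
method-comparison and label-noise reports. Every function is a pure
composition of the public module APIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classical, metrics, pix2pix, unet
from .pairs_io import ImagePair
from .phantom import CorruptionSpec, corrupt_labels

__all__ = [
    "MethodSetup",
    "train_method",
    "segment_with",
    "score_cohort",
    "run_comparison",
    "run_label_noise",
]

LEARNED_METHODS = ("pix2pix", "unet")
CLASSICAL_METHODS = ("otsu", "canny")


@dataclass
class MethodSetup:
    """Everything needed to train/apply one method at one problem size."""

    method: str
    image_size: int = 64
    base_channels: int = 16
    config: pix2pix.TrainConfig = field(default_factory=pix2pix.TrainConfig)
    canny_params: classical.CannyParams = field(default_factory=classical.CannyParams)
    unet_depth: int = 4
    patch_depth: int = 3

    def __post_init__(self):
        if self.method not in LEARNED_METHODS + CLASSICAL_METHODS:
            raise ValueError(f"unknown method {self.method!r}")


def train_method(setup: MethodSetup, train_pairs: list[ImagePair]):
    """Train a learned method; classical methods return None (no training)."""
    if setup.method == "pix2pix":
        gspec = pix2pix.GeneratorSpec(input_size=setup.image_size,
                                      base_channels=setup.base_channels)
        dspec = pix2pix.DiscriminatorSpec(patch_depth=setup.patch_depth,
                                          base_channels=setup.base_channels)
        return pix2pix.train(train_pairs, gspec, dspec, setup.config)
    if setup.method == "unet":
        uspec = unet.UNetSpec(input_size=setup.image_size,
                              base_channels=setup.base_channels,
                              depth=setup.unet_depth)
        return unet.train_unet(train_pairs, uspec, setup.config)
    return None


def segment_with(setup: MethodSetup, model, image: np.ndarray) -> np.ndarray:
    if setup.method == "pix2pix":
        return pix2pix.segment(model, image)
    if setup.method == "unet":
        return unet.segment_unet(model, image)
    if setup.method == "otsu":
        return classical.otsu_threshold(image)[1]
    return classical.canny_mask(image, setup.canny_params)


def score_cohort(setup: MethodSetup, model, pairs: list[ImagePair],
                 against_clean: bool = True) -> list[metrics.MetricRecord]:
    """Score predictions for a cohort against its (clean by default) masks."""
    records = []
    for p in pairs:
        ref = p.reference_mask if against_clean else p.mask
        pred = segment_with(setup, model, p.image)
        records.append(metrics.score(pred, ref, pair_id=p.pair_id))
    return records


def run_comparison(methods: list[str], train_pairs: list[ImagePair],
                   test_pairs: list[ImagePair], image_size: int,
                   base_channels: int, config: pix2pix.TrainConfig) -> list[dict]:
    """Train/apply each method on one shared split; one comparison row each."""
    per_method = {}
    for name in methods:
        setup = MethodSetup(method=name, image_size=image_size,
                            base_channels=base_channels, config=config)
        model = train_method(setup, train_pairs)
        per_method[name] = score_cohort(setup, model, test_pairs)
    return metrics.compare_methods(per_method)


def run_label_noise(train_pairs: list[ImagePair], test_pairs: list[ImagePair],
                    corruption: CorruptionSpec, image_size: int,
                    base_channels: int, config: pix2pix.TrainConfig,
                    seed: int = 0) -> dict:
    """Train the translator on corrupted labels; report test performance
    against both the corrupted and the clean references."""
    bad_train = corrupt_labels(train_pairs, corruption, seed=seed)
    bad_test = corrupt_labels(test_pairs, corruption, seed=seed + 1)
    setup = MethodSetup(method="pix2pix", image_size=image_size,
                        base_channels=base_channels, config=config)
    model = train_method(setup, bad_train)
    vs_corrupted = score_cohort(setup, model, bad_test, against_clean=False)
    vs_clean = score_cohort(setup, model, bad_test, against_clean=True)
    return {"model": model, "vs_corrupted": vs_corrupted, "vs_clean": vs_clean}
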