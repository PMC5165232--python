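"""Seeded synthetic images and feature datasets.

Two generators cover the two stages that need test data:

* block-textured images realize the fine-vs-coarse contrast that drives
  run-length statistics — small blocks give many short runs (fine
  texture), large blocks give long runs (coarse texture);
* nodule phantoms place a bright disk on a darker noisy background for
  segmentation tests, with an exact ground-truth mask.

Five texture archetypes stand in for the five tissue classes (four
nodule types plus healthy parenchyma).  The mapping from archetype to
clinical class is arbitrary: no per-class texture model is claimed, only
that the classes are statistically distinct in the 12 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import GrayImage
from .texture import FEATURE_NAMES, feature_vector

DEFAULT_G = 8


@dataclass(frozen=True)
class TextureSpec:
    """Block-texture archetype for one class.

    ``block_size`` 1 means every pixel drawn independently (fine texture);
    larger blocks yield coarse texture.  ``gray_level_distribution`` is a
    probability vector over the G gray levels; ``noise_flip_prob`` is the
    per-pixel probability of resampling the level after tiling.
    """

    class_id: int
    block_size: int
    gray_level_distribution: tuple[float, ...]
    noise_flip_prob: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.gray_level_distribution, dtype=float)
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("gray_level_distribution must sum to 1")
        if p.min() < 0:
            raise ValueError("probabilities must be nonnegative")
        if not 0.0 <= self.noise_flip_prob <= 1.0:
            raise ValueError("noise_flip_prob must lie in [0, 1]")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


@dataclass(frozen=True)
class NoduleImageSpec:
    """Bright-disk phantom: geometry and intensity of the segmentation fixture."""

    image_size: int = 64
    nodule_radius: int = 10
    nodule_intensity: int = 220
    background_mean: float = 60.0
    background_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.nodule_radius < self.image_size / 2:
            raise ValueError("nodule_radius must lie in [0, image_size/2)")
        if not 0 <= self.nodule_intensity <= 255:
            raise ValueError("nodule_intensity must lie in [0, 255]")


def generate_texture_image(spec: TextureSpec, size: int,
                           rng: np.random.Generator) -> GrayImage:
    """One size×size block-textured image drawn from the spec.

    The image is tiled by constant ``block_size`` squares with gray levels
    drawn i.i.d. from the class distribution, then each pixel is
    independently resampled from the same distribution with probability
    ``noise_flip_prob``.
    """
    if size < 8:
        raise ValueError("size must be >= 8")
    if spec.block_size > size:
        raise ValueError("block_size must not exceed the image size")
    g = len(spec.gray_level_distribution)
    p = np.asarray(spec.gray_level_distribution, dtype=float)
    n_blocks = -(-size // spec.block_size)          # ceil division
    blocks = rng.choice(g, size=(n_blocks, n_blocks), p=p)
    px = np.repeat(np.repeat(blocks, spec.block_size, axis=0),
                   spec.block_size, axis=1)[:size, :size]
    if spec.noise_flip_prob > 0:
        flip = rng.uniform(size=px.shape) < spec.noise_flip_prob
        px = np.where(flip, rng.choice(g, size=px.shape, p=p), px)
    return GrayImage(px.astype(np.intp), g)


def generate_nodule_image(spec: NoduleImageSpec) -> tuple[GrayImage, np.ndarray]:
    """Bright-disk phantom and its exact ground-truth mask.

    The background is truncated-normal noise clipped to [0, 255]; the disk
    (strictly inside radius) is set to the nodule intensity.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    bg = rng.normal(spec.background_mean, spec.background_sd, size=(n, n))
    px = np.clip(np.rint(bg), 0, 255).astype(np.intp)
    center = (n - 1) / 2.0
    rr, cc = np.mgrid[0:n, 0:n]
    mask = (rr - center) ** 2 + (cc - center) ** 2 <= spec.nodule_radius ** 2
    if spec.nodule_radius == 0:
        mask[:] = False
    px[mask] = spec.nodule_intensity
    return GrayImage(px, 256), mask


def default_class_specs(g: int = DEFAULT_G,
                        noise_flip_prob: float = 0.05) -> tuple[TextureSpec, ...]:
    """The five texture archetypes used as the study's synthetic classes.

    Block sizes 1, 2, 4, 8, 16 span fine to coarse texture, and each class
    concentrates its gray-level mass on a different part of the range, so
    both run-length and co-occurrence features separate the classes.
    """
    def peaked(center: int, width: float) -> tuple[float, ...]:
        levels = np.arange(g)
        w = np.exp(-((levels - center) / width) ** 2)
        return tuple(w / w.sum())

    block_sizes = (1, 2, 4, 8, 16)
    centers = (1, 3, 5, 6, 2)
    widths = (1.0, 1.5, 1.0, 2.0, 3.0)
    return tuple(
        TextureSpec(class_id=k, block_size=b,
                    gray_level_distribution=peaked(c, w),
                    noise_flip_prob=noise_flip_prob)
        for k, (b, c, w) in enumerate(zip(block_sizes, centers, widths)))


def generate_labeled_dataset(n_per_class: int,
                             specs: tuple[TextureSpec, ...] | None = None,
                             rng: np.random.Generator | None = None,
                             size: int = 32, distance: int = 1
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class-balanced 12-feature dataset computed from generated textures.

    Returns ``(features, one_hot_targets, labels)`` with ``features`` of
    shape (n_per_class * n_classes, 12) in FEATURE_NAMES order.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    specs = default_class_specs() if specs is None else specs
    rng = np.random.default_rng() if rng is None else rng
    n_classes = len(specs)
    rows, labels = [], []
    for spec in specs:
        for _ in range(n_per_class):
            img = generate_texture_image(spec, size, rng)
            feats = feature_vector(img, distance=distance)
            rows.append([feats[name] for name in FEATURE_NAMES])
            labels.append(spec.class_id)
    features = np.asarray(rows, dtype=float)
    labels = np.asarray(labels, dtype=int)
    one_hot = np.eye(n_classes)[labels]
    return features, one_hot, labels
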