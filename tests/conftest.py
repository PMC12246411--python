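"""Shared fixtures: rasterized shapes and synthetic lesion datasets."""

from __future__ import annotations

import numpy as np
import pytest

from dermaseq.synthetic_lesions import benchmark_class_specs, generate_dataset


def rasterize_disk(radius: float, n: int, center=None) -> np.ndarray:
    """Filled disk on an n x n grid (bool)."""
    yy, xx = np.mgrid[:n, :n]
    cy, cx = center if center is not None else (n // 2, n // 2)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def rasterize_ellipse(a: float, b: float, n: int) -> np.ndarray:
    """Axis-aligned filled ellipse, semi-axes (a rows, b cols)."""
    yy, xx = np.mgrid[:n, :n]
    c = n // 2
    return ((yy - c) / a) ** 2 + ((xx - c) / b) ** 2 <= 1.0


def flat_rgb(mask: np.ndarray, fg: int = 80, bg: int = 200) -> np.ndarray:
    """Uniform-intensity RGB image from a binary mask."""
    plane = np.where(mask, fg, bg).astype(np.uint8)
    return np.dstack([plane] * 3)


@pytest.fixture(scope="session")
def benchmark_dataset():
    """3-class synthetic benchmark: 600 images, 64 x 64, fixed seed."""
    specs = benchmark_class_specs(image_size=(64, 64))
    images = generate_dataset(specs, n_per_class=200, seed=11)
    X = np.stack([im.pixels for im in images])
    y = [im.spec.class_label for im in images]
    return X, y, images


@pytest.fixture(scope="session")
def small_two_class_dataset():
    """2-class linearly separable set: 200 images, 64 x 64."""
    grid = benchmark_class_specs(image_size=(64, 64))
    specs = {k: grid[k] for k in ("small_smooth", "large_irregular")}
    images = generate_dataset(specs, n_per_class=100, seed=7)
    X = np.stack([im.pixels for im in images])
    y = np.array([im.spec.class_label for im in images])
    order = np.random.default_rng(7).permutation(len(X))
    return X[order], list(y[order])
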