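"""Clean test imagery and training corpora.

Three generators cover the experimental needs of the despeckler without any
external data: a piecewise-constant geometric phantom (rectangle, lines of
varied width and orientation, a small disk) for PSNR/SSIM experiments, a
cyst-style phantom (dark cysts, bright scatterers, point targets on a
mid-grey bed) whose returned ROI list drives ENL/CNR evaluation, and a
randomized mixed corpus for unsupervised filter learning.  These are
geometric stand-ins, not acoustic simulations: they reproduce the region
structure that the evaluation metrics need, not ultrasound physics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .metrics import ROI
from .speckle import SpeckleParams, add_speckle

__all__ = ["ROIPair", "make_geometric_phantom", "make_cyst_phantom", "make_training_corpus"]


@dataclass(frozen=True)
class ROIPair:
    """An object region with a matched nearby background region."""

    kind: str  # "cyst" or "scatterer"
    object: ROI
    background: ROI


def _disk_mask(shape: tuple[int, int], centre: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius**2


def make_geometric_phantom(size: tuple[int, int] = (256, 256), seed: int = 0) -> np.ndarray:
    """Piecewise-constant phantom: rectangle, lines, and a small disk.

    Deterministic given the seed, which jitters the primitive positions by
    a few pixels.  Background is mid-grey; at least three distinct
    intensity levels are always present.
    """
    H, W = size
    if H < 64 or W < 64:
        raise ValueError(f"size must be at least 64x64, got {size}")
    rng = np.random.default_rng(seed)
    img = np.full((H, W), 120.0)

    def jit(lo: int, hi: int) -> int:
        return int(rng.integers(lo, hi + 1))

    # filled rectangle, upper-left quadrant
    t, l = H // 8 + jit(-3, 3), W // 8 + jit(-3, 3)
    img[t : t + H // 4, l : l + W // 4] = 200.0
    # horizontal line, 1 px
    r = 5 * H // 8 + jit(-2, 2)
    img[r, W // 10 : 9 * W // 10] = 40.0
    # vertical line, 3 px
    c = 3 * W // 4 + jit(-2, 2)
    img[H // 10 : 9 * H // 10, c : c + 3] = 220.0
    # diagonal line, ~2 px wide
    d0 = jit(-2, 2)
    for k in range(H // 8, 7 * H // 8):
        j = int(W // 2 + 0.6 * (k - H // 2)) + d0
        if 0 <= j < W - 1:
            img[k, j : j + 2] = 60.0
    # small disk ("circular point")
    cy, cx = 3 * H // 4 + jit(-3, 3), W // 4 + jit(-3, 3)
    img[_disk_mask((H, W), (cy, cx), 8.0)] = 240.0
    return img


def make_cyst_phantom(
    size: tuple[int, int] = (256, 256), seed: int = 0
) -> tuple[np.ndarray, list[ROIPair]]:
    """Cyst-style phantom with machine-readable evaluation regions.

    Five dark disks (cysts), five bright disks (strongly scattering
    regions) and a column of isolated bright point targets sit on a
    mid-grey bed carrying a faint smooth texture.  Returns the clean image
    and one ``ROIPair`` (object square inscribed in the disk, matched
    background square beside it) per cyst and scatterer.
    """
    H, W = size
    if H < 128 or W < 128:
        raise ValueError(f"size must be at least 128x128, got {size}")
    rng = np.random.default_rng(seed)
    base = 130.0
    # faint smooth texture so the bed is not perfectly flat
    img = base + ndimage.gaussian_filter(rng.normal(0.0, 8.0, size), 4.0)

    radius = max(7.0, min(H, W) / 18.0)
    half = int(radius / np.sqrt(2.0)) - 1  # inscribed square half-side
    rois: list[ROIPair] = []
    rows = np.linspace(0.15 * H, 0.85 * H, 5)
    for kind, col_frac, level in (("cyst", 0.22, 45.0), ("scatterer", 0.62, 215.0)):
        for row in rows:
            cy = int(row + rng.integers(-2, 3))
            cx = int(col_frac * W + rng.integers(-2, 3))
            img[_disk_mask((H, W), (cy, cx), radius)] = level
            obj = ROI(cy - half, cx - half, 2 * half + 1, 2 * half + 1, role="object", label=kind)
            bg_left = cx + int(radius) + 4
            bg = ROI(cy - half, bg_left, 2 * half + 1, 2 * half + 1, role="background", label="bed")
            rois.append(ROIPair(kind=kind, object=obj, background=bg))
    # column of isolated bright point targets
    cx = int(0.9 * W)
    for row in np.linspace(0.1 * H, 0.9 * H, 7):
        img[_disk_mask((H, W), (float(row), cx), 1.2)] = 255.0
    return np.clip(img, 0.0, 255.0), rois


def make_training_corpus(
    n: int = 20,
    size: tuple[int, int] = (128, 128),
    sigma: float = 3.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Speckle-corrupted mixed phantom corpus for filter learning.

    Alternates geometric and cyst scenes with per-image randomized
    geometry and noise; ``sigma = 0`` yields a noise-free corpus.  Purely
    deterministic in (n, size, sigma, seed).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n) % (2**31)
    corpus = []
    for i in range(n):
        scene_seed = int(child_seeds[2 * i])
        if i % 2 == 0:
            clean = make_geometric_phantom(size, seed=scene_seed)
        else:
            clean, _ = make_cyst_phantom(
                (max(size[0], 128), max(size[1], 128)), seed=scene_seed
            )
            clean = clean[: size[0], : size[1]]
        noisy = add_speckle(
            clean, SpeckleParams(sigma=sigma, seed=int(child_seeds[2 * i + 1]))
        )
        corpus.append(noisy)
    return corpus
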