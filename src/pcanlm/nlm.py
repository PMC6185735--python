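"""Feature-based nonlocal-means despeckling.

Each pixel is restored as a weighted mean over a search window; the weight
between two pixels is ``exp(-D / h**2)`` where ``D`` is a Gaussian-weighted
squared distance between their patch descriptors.  The descriptor is either
the raw intensity patch (classical NLM, Pearson-distance pre-filter) or the
concatenation of patches cut from learned feature maps.  The full pipeline
pre-filters the noisy image, extracts features from the pre-filtered image,
restores the original image, then refines the weights once more using
features of the restored image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve

from .pcanet import PCANetModel, extract_features
from .speckle import estimate_noise_std

__all__ = [
    "NLMConfig",
    "FeatureVector",
    "build_feature_vector",
    "similarity_weight",
    "nlm_restore",
    "pearson_nlm_prefilter",
    "tnlm_baseline",
    "despeckle",
]


@dataclass(frozen=True)
class NLMConfig:
    """Tunables of the nonlocal-means weight and window geometry.

    Parameters
    ----------
    sim_window : int
        Odd side of the similarity patch used as pixel descriptor.
    search_window : int
        Odd side of the region whose pixels are averaged.
    beta : float
        Multiplier in the decay-parameter rule ``h = beta * sigma`` used by
        the intensity- and feature-domain filters.
    prefilter_beta : float
        Decay multiplier of the Pearson-distance pre-filter.  The Pearson
        distance divides the squared patch difference by the local
        intensity, which removes the signal dependence of the speckle
        variance, so its natural distance scale (about ``2 * sigma**2``)
        differs from the raw intensity scale by a factor of the mean
        brightness; it therefore needs its own, much smaller, multiplier.
    sigma : float or None
        Noise standard deviation; estimated from the input when None.
    alpha : float or None
        Std (in pixel offsets) of the Gaussian that down-weights patch
        entries far from the centre; defaults to ``sim_window / 4``.
    normalize_distance : bool
        Divide the squared feature distance by the number of feature maps
        so one ``h`` scale works for any bank size.
    """

    sim_window: int = 7
    search_window: int = 17
    beta: float = 20.0
    prefilter_beta: float = 0.6
    sigma: float | None = None
    alpha: float | None = None
    normalize_distance: bool = True

    def __post_init__(self) -> None:
        for name, w in (("sim_window", self.sim_window), ("search_window", self.search_window)):
            if w < 1 or w % 2 == 0:
                raise ValueError(f"{name} must be an odd positive integer, got {w}")
        if self.sim_window > self.search_window:
            raise ValueError("sim_window must not exceed search_window")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.prefilter_beta <= 0:
            raise ValueError(f"prefilter_beta must be positive, got {self.prefilter_beta}")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")

    @property
    def h(self) -> float:
        """Decay parameter ``beta * sigma``; requires sigma to be set."""
        if self.sigma is None:
            raise ValueError("sigma is not set; estimate it or pass it explicitly")
        return self.beta * self.sigma

    def spatial_kernel(self) -> np.ndarray:
        """Normalized Gaussian over patch offsets (sums to 1)."""
        alpha = self.alpha if self.alpha is not None else self.sim_window / 4.0
        half = self.sim_window // 2
        off = np.arange(-half, half + 1)
        g1 = np.exp(-(off**2) / (2.0 * alpha**2))
        g = np.outer(g1, g1)
        return g / g.sum()


@dataclass(frozen=True)
class FeatureVector:
    """A pixel's descriptor: stacked sim_window patches from all L maps.

    ``values`` has shape (L, sim_window, sim_window); ``offsets`` the
    (dy, dx) offset of each in-patch position, shared across maps.
    """

    values: np.ndarray
    offsets: np.ndarray

    def __len__(self) -> int:
        return int(np.prod(self.values.shape))


def _as_stack(features: np.ndarray) -> np.ndarray:
    f = np.asarray(features, dtype=np.float64)
    if f.ndim == 2:
        f = f[np.newaxis]
    if f.ndim != 3:
        raise ValueError(f"feature stack must be (L, H, W), got shape {f.shape}")
    return f


def build_feature_vector(
    features: np.ndarray, centre: tuple[int, int], config: NLMConfig
) -> FeatureVector:
    """Cut the sim_window patch around ``centre`` from every feature map.

    Boundary patches use symmetric padding, matching the map extraction
    convention, so every pixel has a full-length descriptor.
    """
    f = _as_stack(features)
    i, j = centre
    if not (0 <= i < f.shape[1] and 0 <= j < f.shape[2]):
        raise ValueError(f"centre {centre} outside image of shape {f.shape[1:]}")
    half = config.sim_window // 2
    fpad = np.pad(f, ((0, 0), (half, half), (half, half)), mode="symmetric")
    patch = fpad[:, i : i + config.sim_window, j : j + config.sim_window]
    off = np.arange(-half, half + 1)
    dy, dx = np.meshgrid(off, off, indexing="ij")
    return FeatureVector(values=patch.copy(), offsets=np.stack([dy, dx], axis=-1))


def _weighted_sq_distance(xi: FeatureVector, xj: FeatureVector, config: NLMConfig) -> float:
    if xi.values.shape != xj.values.shape:
        raise ValueError("feature vectors have mismatched lengths")
    g = config.spatial_kernel()
    d = float((((xi.values - xj.values) ** 2) * g).sum())
    if config.normalize_distance:
        d /= xi.values.shape[0]
    return d


def similarity_weight(xi: FeatureVector, xj: FeatureVector, config: NLMConfig) -> float:
    """Patch-similarity weight ``exp(-D / h**2)`` in (0, 1].

    ``D`` is the squared Euclidean distance between the descriptors with
    each in-patch position weighted by a normalized Gaussian of std alpha
    (shared across the L maps) and, when ``normalize_distance`` is on,
    divided by L.
    """
    h = config.h
    if h <= 0:
        raise ValueError("decay parameter h must be positive")
    return float(np.exp(-_weighted_sq_distance(xi, xj, config) / h**2))


def _nlm_offset_sweep(
    noisy: np.ndarray,
    sq_channel_sum,
    config: NLMConfig,
    h: float,
    n_maps: int,
) -> np.ndarray:
    """Shared offset-sweep engine for all NLM variants.

    ``sq_channel_sum(dy, dx, ys, xs)`` must return the per-pixel sum over
    descriptor channels of the squared (or Pearson-normalized) difference
    between the padded descriptor maps and their (dy, dx)-shifted copy, on
    the padded grid covering image rows ``ys`` and columns ``xs`` plus the
    patch apron.  The sweep Gaussian-aggregates it over the similarity
    patch, exponentiates, and accumulates the weighted mean.  The search
    window is truncated at the borders (no invented intensities); the
    centre offset contributes self-weight exp(0) = 1.
    """
    u = np.asarray(noisy, dtype=np.float64)
    H, W = u.shape
    S = config.search_window // 2
    g = config.spatial_kernel()
    num = np.zeros((H, W))
    den = np.zeros((H, W))
    inv_h2 = 0.0 if np.isinf(h) else 1.0 / h**2
    for dy in range(-S, S + 1):
        for dx in range(-S, S + 1):
            y0, y1 = max(0, -dy), min(H, H - dy)
            x0, x1 = max(0, -dx), min(W, W - dx)
            if y0 >= y1 or x0 >= x1:
                continue
            if dy == 0 and dx == 0:
                w = np.ones((H, W))
                num += w * u
                den += w
                continue
            sq = sq_channel_sum(dy, dx, (y0, y1), (x0, x1))
            dist = fftconvolve(sq, g, mode="valid")
            if config.normalize_distance:
                dist /= n_maps
            w = np.exp(-np.maximum(dist, 0.0) * inv_h2)
            num[y0:y1, x0:x1] += w * u[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
            den[y0:y1, x0:x1] += w
    return num / den


def nlm_restore(
    noisy: np.ndarray,
    features: np.ndarray,
    config: NLMConfig,
    h: float | None = None,
) -> np.ndarray:
    """Restore an image by feature-weighted nonlocal averaging.

    Every output pixel is the weighted mean of the noisy intensities in its
    search window; weights come from ``similarity_weight`` applied to the
    feature descriptors.  ``features`` is an (L, H, W) stack aligned with
    the image (a single 2-D map is accepted and treated as L = 1).
    """
    u = np.asarray(noisy, dtype=np.float64)
    f = _as_stack(features)
    if f.shape[1:] != u.shape:
        raise ValueError(f"features {f.shape[1:]} not aligned with image {u.shape}")
    if h is None:
        h = config.h
    if h <= 0:
        raise ValueError("decay parameter h must be positive")
    half = config.sim_window // 2
    fpad = np.pad(f, ((0, 0), (half, half), (half, half)), mode="symmetric")

    def sq_sum(dy, dx, ys, xs):
        y0, y1 = ys
        x0, x1 = xs
        a = fpad[:, y0 : y1 + 2 * half, x0 : x1 + 2 * half]
        b = fpad[:, y0 + dy : y1 + dy + 2 * half, x0 + dx : x1 + dx + 2 * half]
        return ((a - b) ** 2).sum(axis=0)

    return _nlm_offset_sweep(u, sq_sum, config, h, f.shape[0])


def pearson_nlm_prefilter(
    noisy: np.ndarray,
    config: NLMConfig,
    h: float | None = None,
    eps: float = 1.0,
) -> np.ndarray:
    """Intensity-domain NLM with the Pearson patch distance.

    The squared patch difference is normalized by the candidate patch's
    intensity, ``(u(p_i) - u(p_j))**2 / u(p_j)``, which equalizes the
    signal-dependent speckle variance across brightness levels (the
    Bayesian-NLM despeckling distance).  Intensities are floored at ``eps``
    in the denominator, never rejected.  The decay parameter defaults to
    ``prefilter_beta * sigma``.
    """
    u = np.asarray(noisy, dtype=np.float64)
    if u.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {u.shape}")
    if h is None:
        if config.sigma is None:
            config = replace(config, sigma=estimate_noise_std(u))
        h = config.prefilter_beta * config.sigma
    if h <= 0:
        raise ValueError("decay parameter h must be positive")
    half = config.sim_window // 2
    upad = np.pad(u, half, mode="symmetric")
    floor = np.maximum(upad, eps)

    def sq_sum(dy, dx, ys, xs):
        y0, y1 = ys
        x0, x1 = xs
        a = upad[y0 : y1 + 2 * half, x0 : x1 + 2 * half]
        b = upad[y0 + dy : y1 + dy + 2 * half, x0 + dx : x1 + dx + 2 * half]
        fb = floor[y0 + dy : y1 + dy + 2 * half, x0 + dx : x1 + dx + 2 * half]
        return (a - b) ** 2 / fb

    return _nlm_offset_sweep(u, sq_sum, config, h, 1)


def tnlm_baseline(
    noisy: np.ndarray, config: NLMConfig, h: float | None = None
) -> np.ndarray:
    """Classical intensity-based NLM: descriptors are raw noisy patches.

    Definitionally identical to ``nlm_restore`` with the single feature map
    equal to the noisy image itself.
    """
    u = np.asarray(noisy, dtype=np.float64)
    if h is None:
        if config.sigma is None:
            config = replace(config, sigma=estimate_noise_std(u))
        h = config.h
    return nlm_restore(u, u[np.newaxis], config, h=h)


def despeckle(
    noisy: np.ndarray,
    model: PCANetModel,
    config: NLMConfig = NLMConfig(),
    passes: int = 2,
) -> np.ndarray:
    """Full despeckling pipeline.

    1. Estimate sigma (unless given) and pre-filter the noisy image with
       the Pearson-distance NLM.
    2. Extract feature maps from the pre-filtered image.
    3-4. Restore the ORIGINAL noisy image by feature-weighted NLM.
    5-6. For each further pass, re-extract features from the restored
       image and restore the original noisy image again with the refined
       weights.

    Sigma is estimated once from the noisy input and reused everywhere:
    the pre-filter runs at ``prefilter_beta * sigma`` and every restoring
    pass at ``beta * sigma``.  Output is clipped to [0, 255].
    """
    if passes < 1:
        raise ValueError(f"passes must be >= 1, got {passes}")
    u = np.asarray(noisy, dtype=np.float64)
    if config.sigma is None:
        config = replace(config, sigma=estimate_noise_std(u))
    pre = pearson_nlm_prefilter(u, config)
    guide = pre
    restored = u
    for _ in range(passes):
        feats = extract_features(guide, model)
        restored = nlm_restore(u, feats, config)
        guide = restored
    return np.clip(restored, 0.0, 255.0)
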