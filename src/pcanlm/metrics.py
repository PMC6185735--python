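"""Despeckling quality metrics: PSNR, SSIM, ENL and CNR.

PSNR and SSIM require a clean reference; ENL (equivalent number of looks)
and CNR (contrast-to-noise ratio) are reference-free and operate on
rectangular regions of interest.  All statistics use population (not
sample) variance, and PSNR anchors to the 8-bit peak of 255 without
rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["ROI", "SSIMConfig", "psnr", "ssim", "enl", "cnr"]

_PEAK = 255.0


@dataclass(frozen=True)
class ROI:
    """Rectangular region, 0-based, half-open in both axes."""

    top: int
    left: int
    height: int
    width: int
    role: str = "background"
    label: str = ""

    def __post_init__(self) -> None:
        if self.top < 0 or self.left < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.height * self.width < 2:
            raise ValueError("ROI must contain at least 2 pixels")
        if self.role not in ("background", "object"):
            raise ValueError(f"role must be background or object, got {self.role!r}")

    def extract(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image)
        if self.top + self.height > img.shape[0] or self.left + self.width > img.shape[1]:
            raise ValueError(f"ROI {self} exceeds image of shape {img.shape}")
        return img[self.top : self.top + self.height, self.left : self.left + self.width]


@dataclass(frozen=True)
class SSIMConfig:
    """Stabilizers and mode of the structural-similarity index.

    ``windowed`` (the default) averages the index over local 11x11
    Gaussian-weighted windows of std 1.5, the convention of the original
    SSIM definition; ``global`` evaluates the formula once with whole-image
    statistics.
    """

    C1: float = (0.01 * _PEAK) ** 2
    C2: float = (0.03 * _PEAK) ** 2
    mode: str = "windowed"
    window: int = 11
    gaussian_std: float = 1.5
    dynamic_range: float = _PEAK

    def __post_init__(self) -> None:
        if self.C1 <= 0 or self.C2 <= 0:
            raise ValueError("C1 and C2 must be positive")
        if self.mode not in ("global", "windowed"):
            raise ValueError(f"mode must be global or windowed, got {self.mode!r}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def psnr(denoised: np.ndarray, reference: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB against a 255 peak.

    Identical images return positive infinity (the documented zero-MSE
    sentinel).
    """
    d, r = _check_pair(denoised, reference)
    mse = float(np.mean((d - r) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(_PEAK**2 / mse)


def ssim(
    denoised: np.ndarray, reference: np.ndarray, config: SSIMConfig = SSIMConfig()
) -> float:
    """Structural similarity index in [-1, 1]."""
    d, r = _check_pair(denoised, reference)
    if config.mode == "global":
        mu_d, mu_r = d.mean(), r.mean()
        var_d, var_r = d.var(), r.var()
        cov = float(np.mean((d - mu_d) * (r - mu_r)))
        return float(
            (2 * mu_d * mu_r + config.C1)
            * (2 * cov + config.C2)
            / ((mu_d**2 + mu_r**2 + config.C1) * (var_d + var_r + config.C2))
        )
    k1 = np.sqrt(config.C1) / config.dynamic_range
    k2 = np.sqrt(config.C2) / config.dynamic_range
    return float(
        structural_similarity(
            r,
            d,
            win_size=config.window,
            gaussian_weights=True,
            sigma=config.gaussian_std,
            use_sample_covariance=False,
            data_range=config.dynamic_range,
            K1=k1,
            K2=k2,
        )
    )


def enl(image: np.ndarray, roi: ROI) -> float:
    """Equivalent number of looks, ``mean**2 / var``, of a homogeneous ROI.

    Higher means smoother speckle; invariant to multiplying the ROI by a
    positive constant.
    """
    x = roi.extract(np.asarray(image, dtype=np.float64))
    var = float(x.var())
    if var == 0.0:
        raise ValueError(f"zero-variance ROI {roi}: ENL undefined")
    return float(x.mean()) ** 2 / var


def cnr(image: np.ndarray, background: ROI, object: ROI) -> float:
    """Contrast-to-noise ratio ``|mu_b - mu_o| / sqrt(var_b + var_o)``."""
    img = np.asarray(image, dtype=np.float64)
    b = background.extract(img)
    o = object.extract(img)
    denom = float(b.var() + o.var())
    if denom == 0.0:
        raise ValueError("both ROIs are constant: CNR undefined")
    return abs(float(b.mean()) - float(o.mean())) / np.sqrt(denom)
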