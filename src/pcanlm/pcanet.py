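"""Two-stage PCA convolutional filter learning and feature extraction.

The network is a cascade of two convolutional layers whose kernels are the
leading eigenvectors of the scatter matrix of mean-removed image patches
(classic PCANet filter learning), followed by a pointwise output activation.
Training is entirely unsupervised and closed form: no gradients, no
regularizers.  The default output layer is a PReLU with slope 0.25 on the
negative branch, which keeps the sign structure of the filter responses;
ReLU, sigmoid and the original binary-hash output are available for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

__all__ = [
    "PatchConfig",
    "ActivationSpec",
    "FilterBank",
    "PCANetModel",
    "extract_patches",
    "learn_pca_filters",
    "train_pcanet",
    "apply_activation",
    "extract_features",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1
_PAD_MODES = {"symmetric": "reflect", "zero": "constant"}


@dataclass(frozen=True)
class PatchConfig:
    """Patch geometry shared by both convolutional stages (odd sides)."""

    k1: int = 7
    k2: int = 7

    def __post_init__(self) -> None:
        for name, k in (("k1", self.k1), ("k2", self.k2)):
            if k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be an odd positive integer, got {k}")

    @property
    def size(self) -> int:
        return self.k1 * self.k2


@dataclass(frozen=True)
class ActivationSpec:
    """Output-layer nonlinearity.

    ``prelu`` is the identity for positive responses and ``a * x`` for
    non-positive ones; ``relu`` is the ``a = 0`` special case; ``sigmoid``
    is the logistic function; ``hash`` reproduces the original PCANet
    output (Heaviside binarization of each second-stage map followed by a
    ``2**(w-1)``-weighted sum across the L2 maps of each first-stage
    channel, giving integer-valued maps).
    """

    kind: str = "prelu"
    a: float = 0.25

    def __post_init__(self) -> None:
        if self.kind not in ("prelu", "relu", "sigmoid", "hash"):
            raise ValueError(f"unknown activation kind {self.kind!r}")
        if self.a < 0:
            raise ValueError(f"PReLU slope must be non-negative, got {self.a}")


@dataclass(frozen=True)
class FilterBank:
    """An ordered set of learned 2-D kernels with their PCA eigenvalues.

    ``kernels`` has shape (L, k1, k2); vectorized kernels are orthonormal
    and ``eigenvalues`` is non-increasing.
    """

    kernels: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        if self.kernels.ndim != 3:
            raise ValueError("kernels must have shape (L, k1, k2)")
        if len(self.eigenvalues) != len(self.kernels):
            raise ValueError("one eigenvalue per kernel required")

    def __len__(self) -> int:
        return len(self.kernels)


@dataclass(frozen=True)
class PCANetModel:
    stage1: FilterBank
    stage2: FilterBank
    patch: PatchConfig = field(default_factory=PatchConfig)
    activation: ActivationSpec = field(default_factory=ActivationSpec)
    padding: str = "symmetric"
    #: subtract each patch's mean during convolution as well as training;
    #: off by default (plain linear filtering at inference).
    center_patches: bool = False

    def __post_init__(self) -> None:
        if self.padding not in _PAD_MODES:
            raise ValueError(f"padding must be one of {sorted(_PAD_MODES)}")
        for bank in (self.stage1, self.stage2):
            if bank.kernels.shape[1:] != (self.patch.k1, self.patch.k2):
                raise ValueError("filter banks must match the patch shape")

    @property
    def n_features(self) -> int:
        """Number of feature maps produced per image."""
        if self.activation.kind == "hash":
            return len(self.stage1)
        return len(self.stage1) * len(self.stage2)


def extract_patches(
    image: np.ndarray, patch: PatchConfig, padding: str | None = "symmetric"
) -> np.ndarray:
    """Collect all mean-removed vectorized patches of an image.

    With ``padding`` set (the default), one patch is taken around every
    pixel using symmetric boundary extension, so the column count equals
    H*W.  With ``padding=None`` only fully interior placements are kept.

    Returns an array of shape (k1*k2, n_patches) whose columns each sum to
    zero (per-patch mean removed).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.shape[0] < patch.k1 or img.shape[1] < patch.k2:
        raise ValueError(
            f"image {img.shape} smaller than patch ({patch.k1}, {patch.k2})"
        )
    if padding is not None:
        if padding not in _PAD_MODES:
            raise ValueError(f"padding must be None or one of {sorted(_PAD_MODES)}")
        mode = "symmetric" if padding == "symmetric" else "constant"
        img = np.pad(img, ((patch.k1 // 2,) * 2, (patch.k2 // 2,) * 2), mode=mode)
    windows = sliding_window_view(img, (patch.k1, patch.k2))
    cols = windows.reshape(-1, patch.size).T.copy()
    cols -= cols.mean(axis=0, keepdims=True)
    return cols


def _bank_from_scatter(scatter: np.ndarray, L: int, k1: int, k2: int) -> FilterBank:
    """Top-L eigenvectors of a patch scatter matrix, reshaped to kernels."""
    if L > scatter.shape[0]:
        raise ValueError(f"L={L} exceeds patch dimension {scatter.shape[0]}")
    if not np.any(scatter):
        raise ValueError("degenerate input: patch scatter matrix is all zero")
    evals, evecs = np.linalg.eigh(scatter)
    order = np.argsort(evals)[::-1][:L]
    evals = evals[order]
    evecs = evecs[:, order]
    # eigenvector sign is arbitrary; pin it for reproducibility
    for j in range(L):
        peak = np.argmax(np.abs(evecs[:, j]))
        if evecs[peak, j] < 0:
            evecs[:, j] = -evecs[:, j]
    kernels = evecs.T.reshape(L, k1, k2).copy()
    return FilterBank(kernels=kernels, eigenvalues=np.maximum(evals, 0.0))


def learn_pca_filters(patches: np.ndarray, L: int) -> FilterBank:
    """Learn L orthonormal convolution kernels from a mean-removed patch matrix.

    The kernels are the L leading eigenvectors of ``A @ A.T`` (equivalently
    the minimizers of the patch reconstruction error over orthonormal
    bases), reshaped to square kernels.  The patch side is inferred from the
    row count, which must be a perfect square of an odd number.
    """
    A = np.asarray(patches, dtype=np.float64)
    if A.ndim != 2 or A.shape[1] == 0:
        raise ValueError("patch matrix must be 2-D and non-empty")
    k = int(round(np.sqrt(A.shape[0])))
    if k * k != A.shape[0]:
        raise ValueError(f"patch dimension {A.shape[0]} is not a perfect square")
    return _bank_from_scatter(A @ A.T, L, k, k)


def _correlate(image: np.ndarray, kernel: np.ndarray, padding: str) -> np.ndarray:
    return ndimage.correlate(image, kernel, mode=_PAD_MODES[padding], cval=0.0)


def _stage_responses(
    image: np.ndarray, bank: FilterBank, padding: str, center: bool
) -> np.ndarray:
    """Same-size correlation of an image with every kernel of a bank."""
    img = np.asarray(image, dtype=np.float64)
    out = np.empty((len(bank),) + img.shape)
    if center:
        # subtracting the local patch mean == also correlating with a
        # mean-removed kernel against the local-mean map
        k1, k2 = bank.kernels.shape[1:]
        local_mean = ndimage.uniform_filter(
            img, size=(k1, k2), mode=_PAD_MODES[padding], cval=0.0
        )
    for i, kern in enumerate(bank.kernels):
        out[i] = _correlate(img, kern, padding)
        if center:
            out[i] -= kern.sum() * local_mean
    return out


def train_pcanet(
    corpus: list[np.ndarray],
    patch: PatchConfig = PatchConfig(),
    L1: int = 12,
    L2: int = 12,
    activation: ActivationSpec = ActivationSpec(),
    padding: str = "symmetric",
    center_patches: bool = False,
) -> PCANetModel:
    """Learn both filter banks from a training corpus.

    Stage 1 pools the mean-removed patches of every corpus image; each image
    is then filtered with every stage-1 kernel and the patches of all
    resulting response maps are pooled into a single second scatter, whose
    leading L2 eigenvectors form the (shared) stage-2 bank.  Only the
    k1k2 x k1k2 scatter is accumulated per image, so memory stays flat in
    corpus size.  Deterministic given the corpus order.
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    if padding not in _PAD_MODES:
        raise ValueError(f"padding must be one of {sorted(_PAD_MODES)}")

    scatter1 = np.zeros((patch.size, patch.size))
    for img in corpus:
        P = extract_patches(img, patch, padding)
        scatter1 += P @ P.T
    stage1 = _bank_from_scatter(scatter1, L1, patch.k1, patch.k2)

    scatter2 = np.zeros((patch.size, patch.size))
    for img in corpus:
        for resp in _stage_responses(img, stage1, padding, center_patches):
            P = extract_patches(resp, patch, padding)
            scatter2 += P @ P.T
    stage2 = _bank_from_scatter(scatter2, L2, patch.k1, patch.k2)

    return PCANetModel(
        stage1=stage1,
        stage2=stage2,
        patch=patch,
        activation=activation,
        padding=padding,
        center_patches=center_patches,
    )


def apply_activation(x: np.ndarray, spec: ActivationSpec) -> np.ndarray:
    """Elementwise output nonlinearity (prelu / relu / sigmoid)."""
    x = np.asarray(x, dtype=np.float64)
    if spec.kind in ("prelu", "relu"):
        a = spec.a if spec.kind == "prelu" else 0.0
        return np.where(x > 0, x, a * x)
    if spec.kind == "sigmoid":
        # split form avoids overflow for large |x|
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out
    raise ValueError(f"apply_activation does not handle kind={spec.kind!r}")


def extract_features(image: np.ndarray, model: PCANetModel) -> np.ndarray:
    """Per-pixel feature maps of an image under a trained model.

    Returns an array of shape (L, H, W) spatially aligned 1:1 with the
    input: L = L1*L2 activated second-stage responses (map index
    ``v*L2 + w`` for stage-1 channel v, stage-2 filter w), or L = L1
    integer-valued maps for the binary-hash output.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.shape[0] < model.patch.k1 or img.shape[1] < model.patch.k2:
        raise ValueError(f"image {img.shape} smaller than model patch")

    first = _stage_responses(img, model.stage1, model.padding, model.center_patches)
    L2 = len(model.stage2)
    if model.activation.kind == "hash":
        weights = 2.0 ** np.arange(L2)
        out = np.zeros((len(first),) + img.shape)
        for v, fmap in enumerate(first):
            second = _stage_responses(
                fmap, model.stage2, model.padding, model.center_patches
            )
            out[v] = np.tensordot(weights, (second > 0).astype(np.float64), axes=1)
        return out

    out = np.empty((len(first) * L2,) + img.shape)
    for v, fmap in enumerate(first):
        out[v * L2 : (v + 1) * L2] = _stage_responses(
            fmap, model.stage2, model.padding, model.center_patches
        )
    return apply_activation(out, model.activation)


def save_model(model: PCANetModel, path: str | Path) -> None:
    """Serialize a trained model to a single ``.npz`` archive."""
    np.savez(
        Path(path),
        format_version=_FORMAT_VERSION,
        stage1_kernels=model.stage1.kernels,
        stage1_eigenvalues=model.stage1.eigenvalues,
        stage2_kernels=model.stage2.kernels,
        stage2_eigenvalues=model.stage2.eigenvalues,
        patch=np.array([model.patch.k1, model.patch.k2]),
        activation_kind=np.array(model.activation.kind),
        activation_a=model.activation.a,
        padding=np.array(model.padding),
        center_patches=model.center_patches,
    )


def load_model(path: str | Path) -> PCANetModel:
    with np.load(Path(path)) as z:
        version = int(z["format_version"])
        if version != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version}")
        return PCANetModel(
            stage1=FilterBank(z["stage1_kernels"], z["stage1_eigenvalues"]),
            stage2=FilterBank(z["stage2_kernels"], z["stage2_eigenvalues"]),
            patch=PatchConfig(*map(int, z["patch"])),
            activation=ActivationSpec(
                str(z["activation_kind"]), float(z["activation_a"])
            ),
            padding=str(z["padding"]),
            center_patches=bool(z["center_patches"]),
        )
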