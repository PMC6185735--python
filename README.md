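# pcanlm — feature-based nonlocal-means despeckling for ultrasound images

Speckle is the granular, signal-dependent interference pattern of coherent
imaging; in B-mode ultrasound it obscures fine anatomy and complicates
segmentation and diagnosis. `pcanlm` removes speckle with a nonlocal-means
(NLM) filter whose patch-similarity weights are computed not on raw
intensities but on *learned* per-pixel features: the responses of a
two-stage PCA convolutional network (a PCANet-style cascade) with a PReLU
output layer. The package is aimed at medical-image-analysis researchers
who want a fully reproducible, trainable-without-labels despeckler plus the
simulation and evaluation machinery around it.

## The model

Noise model (γ = 0.5 for B-mode speckle):

    u(x, y) = v(x, y) + v(x, y)^γ · η(x, y),      η ~ N(0, σ²)

Filter learning (unsupervised, closed form): collect all k₁×k₂ patches of
the training images, subtract each patch's mean, and stack them as columns
of A. The stage-1 kernels are the L₁ leading eigenvectors of AAᵀ — the
orthonormal basis minimizing ‖A − VVᵀA‖²_F. Each training image is then
filtered with every stage-1 kernel and the procedure repeats on the
response maps to give the L₂ stage-2 kernels. Features of an image are the
L = L₁·L₂ cascade responses through a PReLU output layer
(PReLU(x) = x for x > 0, a·x otherwise, a = 0.25).

Restoration: each pixel is the weighted mean over its 17×17 search window,

    NLM[I(i,j)] = Σ ω(i,j,m,n) I(m,n) / Σ ω(i,j,m,n)
    ω(i,j,m,n)  = exp(−‖X(i,j) − X(m,n)‖²_{2,α} / h²),   h = β·σ̂

where X(i,j) concatenates the 7×7 feature patches around (i,j) from all L
maps, ‖·‖_{2,α} is a Gaussian-weighted Euclidean distance over patch
offsets, and σ̂ is estimated from the noisy image. The pipeline runs in two
passes: a Pearson-distance NLM pre-filter supplies the image whose features
drive pass 1; pass 2 re-extracts features from the pass-1 restoration and
filters the original noisy image again with the refined weights.

## Worked example

```python
import numpy as np
from pcanlm import (NLMConfig, PatchConfig, SpeckleParams, add_speckle,
                    despeckle, estimate_noise_std, make_geometric_phantom,
                    make_training_corpus, psnr, ssim, tnlm_baseline,
                    train_pcanet)

clean = make_geometric_phantom((128, 128), seed=0)
noisy = add_speckle(clean, SpeckleParams(sigma=3.0, seed=7))
corpus = make_training_corpus(n=10, size=(128, 128), sigma=3.0, seed=1)
model = train_pcanet(corpus, PatchConfig(7, 7), L1=4, L2=4)

cfg = NLMConfig()                      # sigma estimated from the input
restored = despeckle(noisy, model, cfg, passes=2)
baseline = tnlm_baseline(noisy, cfg)   # intensity-based NLM for comparison

print(f"estimated sigma : {estimate_noise_std(noisy):.3f}")
print(f"PSNR  noisy / TNLM / despeckled : {psnr(noisy, clean):.2f} / "
      f"{psnr(baseline, clean):.2f} / {psnr(restored, clean):.2f} dB")
print(f"SSIM  noisy / TNLM / despeckled : {ssim(noisy, clean):.3f} / "
      f"{ssim(baseline, clean):.3f} / {ssim(restored, clean):.3f}")
```

Output:

```
estimated sigma : 3.001
PSNR  noisy / TNLM / despeckled : 17.72 / 24.76 / 28.68 dB
SSIM  noisy / TNLM / despeckled : 0.199 / 0.815 / 0.878
```

The noise-level estimate recovers the true σ = 3 to within 0.1 %; the
feature-weighted filter gains ~11 dB PSNR over the noisy input and clearly
improves on the intensity-based NLM baseline in structural similarity.

## Command line

```sh
pcanlm phantom  --kind geometric --size 256 --seed 0 --out clean.png
pcanlm simulate --input clean.png --sigma 3 --seed 0 --output noisy.png
pcanlm train    --n-synthetic 20 --L1 12 --L2 12 --out model.npz
pcanlm despeckle --input noisy.png --model model.npz --passes 2 --output out.png
pcanlm evaluate --ref clean.png --test out.png
pcanlm bench    --size 128 --seed 0        # sigma sweep 3..6, table output
```

`pcanlm train --corpus dir/` learns the filter banks from your own
grayscale PNG/TIFF images instead of the synthetic corpus.

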