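# relcolors

How much Shannon information does a small set of *relevant colors* keep
about an image?

Human observers can reduce a complex painting to a handful of colors they
judge relevant; replacing every pixel by its nearest relevant color is a
quantization of the image. `relcolors` measures how good such a
quantization is in information terms and compares quantizers: five
general clustering methods (k-means++, maximum-entropy clustering,
Gaussian-mixture EM, minCEntropy, Graph-Cut), a colorimetric CIELAB-cell
method that chooses the number of colors automatically, simulated
observer selections, and JPEG compression as a codec baseline.

## The statistic

Treat a randomly drawn pixel's color **a** = (R, G, B) as a discrete
random variable **A** with pmf *p*, estimated by binning the color cube
and counting. The entropy is

    H(A) = − Σ_a p(a) log₂ p(a)        [bits]

and the information a quantized representation **A**_q (the per-pixel
cluster label) retains about the image is the mutual information

    I(A; A_q) = H(A) + H(A_q) − H(A, A_q).

Plug-in entropies are biased downward at small counts, so a
bias-corrected estimator (Grassberger 2003) is available throughout:
Ĥ_G = ln N − (1/N) Σ_i n_i G(n_i), with G(n) built from digamma
functions.

Methods are compared by the **efficiency**

    η = I / I_ref

where *I*_ref is the mutual information achieved by the minCEntropy
reference (the method that directly maximizes I between the binned colors
and the clustering) on the same image at the same number of colors *n*.
Color rendering is measured separately as the mean per-pixel Euclidean
difference in CIECAM02-UCS and in S-CIELAB (opponent-channel
spatial-frequency filtering before CIELAB differencing).

Because the analysis needs ground truth, the package ships a synthetic
generator of painting-like images: *n* color modes with known mixing
proportions, chromatic noise and coherent spatial regions, plus a
simulated observer whose relevant colors are 5×5 patch means around
picked locations.

## Worked example

```python
import numpy as np
from relcolors import (SyntheticSpec, generate_image, true_information,
                       mincentropy_quantize, kmeans_quantize,
                       image_quantization_mi, efficiency)

spec = SyntheticSpec(
    n_true=4,
    palette_true=np.array([[200, 40, 40], [40, 170, 60],
                           [50, 60, 200], [220, 200, 50]]),
    proportions=np.array([0.5, 0.25, 0.125, 0.125]),
    noise_sigma=0.0, layout="stripes", width=64, height=64, seed=11,
)
img, _ = generate_image(spec)
q_ref = mincentropy_quantize(img, 4, seed=0, bin_side=1)
q_km = kmeans_quantize(img, 4, seed=0)
I_ref = image_quantization_mi(img, q_ref, bin_side=1).I
I_km = image_quantization_mi(img, q_km, bin_side=1).I
print(f"analytic mode information: {true_information(spec):.4f} bits")
print(f"minCEntropy I = {I_ref:.4f} bits, k-means I = {I_km:.4f} bits")
print(f"k-means efficiency eta = {efficiency(I_km, I_ref).eta:.4f}")
```

prints

```
analytic mode information: 1.7500 bits
minCEntropy I = 1.7500 bits, k-means I = 1.7500 bits
k-means efficiency eta = 1.0000
```

— on a noise-free image with four well-separated modes at weights
(1/2, 1/4, 1/8, 1/8), every quantizer recovers exactly the mode-label
entropy −Σ w log₂ w = 1.75 bits, and efficiency is 1 by construction.
With chromatic noise the methods separate: the reference stays at η = 1,
clustering methods land slightly below, and simulated observers around
0.9.

A command-line interface wraps the pipeline:

```
quantify synth --out corpus/ --n-images 20      # synthetic corpus + manifest
quantify run --out results/ --n-images 20       # full analysis, CSV outputs
quantify nscan corpus/synth_00.png              # cluster-number estimates
quantify report results/rows.csv                # summaries from saved rows
```

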