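# Methods

## Model and estimators

A pixel drawn uniformly at random from an H×W image is a trivariate
discrete random variable **A** over the 8-bit RGB cube; a quantization to
n relevant colors defines a second variable **A**_q, the per-pixel cluster
label. All information quantities are estimated from histograms:

- `bin_colors` assigns each pixel to the cube `floor(channel / bin_side)`
  per channel. `bin_side` defaults to 8 (32³ cells) for megapixel-scale
  material; the synthetic studies here use `bin_side = 1`, where the
  small gamut of the generated images (a few thousand occupied colors)
  makes binning immaterial.
- The naive (plug-in) entropy is −Σ (c/N) log₂ (c/N) over occupied bins.
- The Grassberger estimator is Ĥ_G = [ln N − (1/N) Σ_i n_i G(n_i)] / ln 2
  with G(n) = ψ(n) + ½(−1)ⁿ[ψ((n+1)/2) − ψ(n/2)]. The correction is
  applied to the two marginals and the joint alike, and the estimator tag
  is recorded in every result. Slightly negative corrected MI values are
  reported as-is; clipping would bias efficiency ratios.
- MI uses the three-entropy identity I = H₁ + H₂ − H₁₂ on the joint
  histogram of (binned color, label) over **all** pixels — subsampling is
  used only inside the clustering steps, never in the estimation.

Efficiency is η = I / I_ref with minCEntropy as the reference, paired
strictly at the same image and the same n. The colorimetric and JPEG
stages, whose n is not free, are paired against a reference re-run at the
colorimetric n, and the observer row entering the color-rendering table
is the one whose n is closest to the colorimetric n (ties toward the
smaller n, flagged in the row's `n_source`).

## Quantizers

All clustering operates on RGB pixel values (a CIELAB option exists but
is off by default), on a seeded uniform subsample of at most 10⁵ pixels
collapsed to distinct colors with multiplicities. Every method returns
exactly the requested n (empty clusters are re-seeded from the farthest
point) and is bit-deterministic given its seed.

- **k-means++ / Lloyd** — textbook D² seeding (no greedy local trials, so
  the selection distribution is exactly the enumerable one) followed by
  weighted Lloyd iterations to an assignment fixpoint, relative objective
  change < 1e-6, or 300 iterations.
- **MEC** — soft memberships of Gibbs form minimizing
  Σ u_ik d_ik + T Σ u_ik ln u_ik, alternating closed-form membership and
  center updates. T defaults to the mean within-cluster variance of the
  k-means++ initialization; T = 0 is the annealing limit and falls back
  to hard k-means (which is also what the default produces on noise-free
  images, where the initial variance is 0).
- **GMM** — full-covariance mixture EM (scikit-learn), k-means++ means
  initialization, covariance floor 1e-3, stepped one EM iteration at a
  time so the per-iteration lower bound forms the objective trace; hard
  labels by maximum responsibility.
- **minCEntropy** — hill climbing on the occupied color bins maximizing
  I(binned color; label). Because each bin carries one label, this equals
  the label entropy, whose maximizer set is highly degenerate: any
  equal-mass partition of the bins attains the maximum. Three choices
  make the method well-behaved without changing the attained objective:
  candidate target clusters are scanned in color-proximity order (so the
  search settles on the color-coherent member of the optimum set and the
  derived palette remains meaningful); stalled climbs escalate to
  pairwise-swap and one-for-two exchange moves, which provably rescue the
  equal-sum local maxima that single-bin moves cannot leave; and several
  seeded restarts (k-means++ first, then random labelings) are kept with
  the best final objective. On small instances this reaches the
  exhaustive optimum; moves never empty a cluster.
- **Graph-Cut** — Potts energy (squared-distance unary scaled by 1/σ²,
  pairwise λ·exp(−‖c_p−c_q‖²/2σ²) over 4-neighbors, λ = 1, σ = 30)
  minimized by iterated alpha-expansion with exact max-flow subproblems
  on a spatially subsampled grid (default cap 128×128; the pipeline runs
  at 32×32 or less for desk-scale studies). Initialization by k-means;
  energy is non-increasing by construction; for two labels a single cut
  is globally optimal.
- **Colorimetric** — CIELAB is divided into cubic cells of side 10
  (origin fixed at (0, −128, −128)); a cell is relevant when its pixel
  share ≥ 0.001, its mean L* lies in [5, 95], and its mean chroma ≥ 5,
  with near-neutral cells exempted when their share ≥ 5×0.001 (grays and
  browns dominate many paintings). Pixels in non-relevant cells take the
  nearest relevant-cell average (CIELAB Euclidean, ties to the lowest
  cell index). n is whatever the designation rule produces. These
  thresholds are declared conventions: the source colorimetric method's
  exact ranges are not published alongside the analysis re-implemented
  here.

### Known limitation: the simplified minCEntropy objective

The original minCEntropy uses a kernel-density conditional-entropy
objective in which color similarity inside a cluster matters. The
histogram formulation implemented here (naive MI of binned colors vs
labels) is exactly maximizable and exactly testable, but it decouples the
objective from color fidelity: at large n its equal-mass clusters render
colors worse than k-means or the colorimetric method even though its MI
is maximal. Consequently the color-rendering *ordering* of methods at the
colorimetric n differs from what a kernel-based reference would give, and
observer efficiencies measured against this reference on noisy images sit
several points below what a color-aware reference would yield (the
reference can "balance" label masses at bin granularity, a headroom no
palette-based quantizer has). Results tables should be read with this in
mind.

## Cluster-number estimation

- Caliński-Harabasz (VRC) and Davies-Bouldin scans run k-means at each
  n in [2, n_max] (presets n_max = 40 and 80), seeded per n from the scan
  seed so curves are reproducible pointwise; n_opt is the argmax/argmin
  and the full index curve is kept in the result.
- Adaptive k-means starts from the mean of the RGB planes, spawns a new
  center at the most distant pixel while any pixel is farther than the
  spawn threshold (default 32 RGB units) from every center, drops empty
  clusters, and Lloyd-iterates to stability; a hard cap of 1024 clusters
  aborts degenerate settings. The spawn-on-distance rule is a declared
  convention for the adaptive variant.

The three estimators are *expected* to disagree with each other and with
observers on realistic images; the test suite asserts only per-method
recovery on well-separated inputs.

## Color difference metrics

RGB is decoded by the standard sRGB transfer and primary matrix to CIE
1931 XYZ (2° observer, Y_white = 100, D65). CIECAM02 viewing conditions
default to D65 white, adapting luminance 64 cd/m², background luminance
factor 20, "average" surround — the analysis only fixes a 6500 K
illuminant, so these are configurable conventions; with incomplete
adaptation (D < 1) the adopted white keeps a residual chroma of ~1 UCS
unit. CAM02-UCS uses the standard (K_L, c₁, c₂) = (1, 0.007, 0.0228)
mapping, and the implementation reproduces the published CIECAM02
verification example to 1e-4.

S-CIELAB transforms XYZ to the opponent channels, filters each with its
sum-of-separable-Gaussians contrast-sensitivity kernel (Zhang-Wandell
spreads; weights renormalized to unit sum so uniform fields pass
unchanged), converts back through XYZ to CIELAB and averages the
per-pixel ΔE*ab. Samples-per-degree defaults to 72 and edge handling is
reflective padding (avoids dark-border artifacts); the viewing geometry
behind any published S-CIELAB number is convention-dependent, so
cross-study comparisons should fix it explicitly.

## Synthetic data

`SyntheticSpec` defines n_true mode colors, mixing proportions, a noise
scale, and a spatial layout (stripes, Voronoi, or multi-site blobs).
Pixel counts per mode are allocated by largest remainder — exact when
w·N is integral — and layouts fill those counts with capacity-constrained
nearest-site assignment, so empirical mode frequencies equal the nominal
proportions to within one pixel. Pixels are the mode color plus clipped
Gaussian noise; everything derives from a named PCG64 generator with
explicit seeds. `true_information` (−Σ w log₂ w) is the analytic MI
oracle for the ideal quantization at zero noise.

The default corpus is 20 images, n_true ∈ [5, 25], Dirichlet(1) weights,
noise σ = 6, palettes rejection-sampled to ≥ 60 RGB units of separation;
image side defaults to 256 but the shipped studies run at 48–96 px so a
full pipeline pass takes minutes on one core. What the generator does
*not* emulate: painterly texture and brushwork, spatially varying
illumination, the long-tailed gamuts of real paintings, and
megapixel-scale color statistics. Passing tests therefore demonstrate the
correctness of the estimators and optimizers and the qualitative ordering
of methods, not the numeric values any particular image corpus would
give. Two desk-scale inversions are expected and documented: JPEG at
quality zero keeps a large fraction of a small image's colors, so its MI
can exceed the reference's (on megapixel paintings the ratio reverses),
and the simplified minCEntropy's rendering error at large n exceeds the
colorimetric method's.

The simulated observer picks one interior location per mode (deepest
point of the region by distance transform), largest modes first, jitters
it by a Gaussian of scale `pick_noise` pixels, takes the 5×5 patch mean
as the relevant color (patches clamped at borders, flagged), and assigns
every pixel to the nearest picked color. With zero jitter on noise-free
images this recovers the mode partition exactly (efficiency 1); jitter
makes picks cross region boundaries or straddle them with the patch,
losing information — the mechanism behind the sub-unity observer
efficiencies.

## Statistics

Confidence limits are 95% BCa bootstrap intervals (scipy), 1000
replicates unless stated; constant inputs short-circuit to a zero-width
interval and a degenerate bootstrap distribution falls back to the
percentile interval, flagged in the result. Group comparisons use the
Kruskal-Wallis rank test with tie correction (all-identical data returns
H = 0, p = 1 by convention). The regression of I on log₂ n is ordinary
least squares with a paired-bootstrap BCa interval on the slope. No
multiple-testing correction is applied anywhere — single rank tests are
reported as-is — which is a documented limitation.

## Determinism

Every public API takes an explicit seed; derived seeds are spawned as
tuples through NumPy's SeedSequence, no global RNG state is touched, and
identical configurations produce byte-identical CSV/JSON outputs, which
the test suite asserts end-to-end.
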