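"""Clustering color quantizers.

Five general optimization methods partition an image's pixel colors into n
clusters ("relevant colors"): k-means++ with Lloyd refinement, maximum-
entropy clustering (MEC, soft Gibbs memberships with an entropy term in
the objective), Gaussian-mixture EM, minCEntropy (hill climbing that
maximizes the mutual information between the binned colors and the
cluster labels), and Graph-Cut (Potts energy minimized by alpha-expansion
on a spatial grid).  Each returns a :class:`Quantization` carrying the
palette, the per-pixel label map, and the objective trace.

Clustering runs on a seeded uniform subsample of distinct colors with
multiplicities; palette application and information estimates always use
all pixels.  Fixed seed implies bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .infotheory import bin_indices

__all__ = [
    "PixelSample",
    "Quantization",
    "sample_pixels",
    "kmeanspp_init",
    "kmeans_quantize",
    "mec_quantize",
    "gmm_quantize",
    "mincentropy_quantize",
    "graphcut_quantize",
    "apply_palette",
    "quantize",
    "CLUSTER_METHODS",
]

DEFAULT_SUBSAMPLE = 100_000
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 300


@dataclass
class PixelSample:
    """Distinct colors with multiplicities, drawn from an image."""

    colors: np.ndarray  # (m, 3) float
    weights: np.ndarray  # (m,) multiplicity >= 1
    source_seed: int = 0

    def __post_init__(self) -> None:
        self.colors = np.asarray(self.colors, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.colors.ndim != 2 or self.colors.shape[1] != 3:
            raise ValueError("colors must be (m, 3)")
        if np.any(self.weights < 1):
            raise ValueError("weights must be >= 1")


@dataclass
class Quantization:
    """A palette of n representative colors plus a per-pixel label map."""

    palette: np.ndarray  # (n, 3) float RGB
    labels: np.ndarray  # (h, w) or flat int
    n: int
    method_tag: str = ""
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    def __post_init__(self) -> None:
        self.palette = np.asarray(self.palette, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.palette.shape != (self.n, 3):
            raise ValueError(f"palette must be ({self.n}, 3)")
        if self.labels.size and (self.labels.max() >= self.n or self.labels.min() < 0):
            raise ValueError("labels must lie in [0, n)")


def sample_pixels(
    image: np.ndarray, max_pixels: int = DEFAULT_SUBSAMPLE, seed: int = 0
) -> PixelSample:
    """Seeded uniform pixel subsample, collapsed to distinct colors + weights."""
    flat = np.asarray(image).reshape(-1, 3)
    if flat.shape[0] > max_pixels:
        rng = np.random.default_rng(seed)
        idx = rng.choice(flat.shape[0], size=max_pixels, replace=False)
        flat = flat[np.sort(idx)]
    colors, weights = np.unique(flat, axis=0, return_counts=True)
    return PixelSample(colors=colors.astype(np.float64), weights=weights, source_seed=seed)


# ---------------------------------------------------------------------------
# k-means++ and Lloyd
# ---------------------------------------------------------------------------


def kmeanspp_init(sample: PixelSample, n: int, seed: int = 0) -> np.ndarray:
    """Classic D^2 seeding on weighted distinct colors.

    The first center is drawn with probability proportional to weight; each
    subsequent center with probability proportional to weight times squared
    distance to the nearest already-chosen center (no greedy local trials,
    so the selection distribution is exactly the textbook one).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    m = sample.colors.shape[0]
    if m < n:
        raise ValueError(f"only {m} distinct colors for n={n} clusters")
    rng = np.random.default_rng(seed)
    w = sample.weights / sample.weights.sum()
    centers = np.empty((n, 3))
    idx = rng.choice(m, p=w)
    centers[0] = sample.colors[idx]
    d2 = ((sample.colors - centers[0]) ** 2).sum(axis=1)
    for k in range(1, n):
        probs = sample.weights * d2
        total = probs.sum()
        if total <= 0:  # all mass on chosen points: pick any unchosen color
            remaining = np.flatnonzero(d2 >= 0)
            chosen_rows = {tuple(c) for c in centers[:k]}
            remaining = [i for i in remaining if tuple(sample.colors[i]) not in chosen_rows]
            idx = remaining[int(rng.integers(len(remaining)))]
        else:
            idx = rng.choice(m, p=probs / total)
        centers[k] = sample.colors[idx]
        d2 = np.minimum(d2, ((sample.colors - centers[k]) ** 2).sum(axis=1))
    return centers


def _assign(colors: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d = ((colors[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d, axis=1)


def _lloyd(
    sample: PixelSample,
    centers: np.ndarray,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """Weighted Lloyd iterations; empty clusters re-seeded from the farthest point."""
    n = centers.shape[0]
    centers = centers.copy()
    labels = _assign(sample.colors, centers)
    trace: list[float] = []
    converged = False
    prev_obj = np.inf
    for _ in range(max_iter):
        for k in range(n):
            mask = labels == k
            if not np.any(mask):
                far = np.argmax(
                    ((sample.colors - centers[labels]) ** 2).sum(axis=1) * sample.weights
                )
                centers[k] = sample.colors[far]
                labels[far] = k
                mask = labels == k
            wk = sample.weights[mask]
            centers[k] = (sample.colors[mask] * wk[:, None]).sum(axis=0) / wk.sum()
        new_labels = _assign(sample.colors, centers)
        obj = float(
            (
                ((sample.colors - centers[new_labels]) ** 2).sum(axis=1) * sample.weights
            ).sum()
        )
        trace.append(obj)
        if np.array_equal(new_labels, labels) or abs(prev_obj - obj) <= tol * max(
            abs(prev_obj), 1.0
        ):
            labels = new_labels
            converged = True
            break
        labels = new_labels
        prev_obj = obj
    return centers, labels, trace, converged


def kmeans_quantize(
    image: np.ndarray,
    n: int,
    seed: int = 0,
    max_pixels: int = DEFAULT_SUBSAMPLE,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> Quantization:
    """k-means++ seeded Lloyd clustering of pixel colors."""
    sample = sample_pixels(image, max_pixels, seed)
    centers = kmeanspp_init(sample, n, seed)
    centers, _, trace, converged = _lloyd(sample, centers, max_iter, tol)
    return _finalize(image, centers, n, "kmeans", trace, converged)


def _finalize(
    image: np.ndarray,
    centers: np.ndarray,
    n: int,
    tag: str,
    trace: list[float],
    converged: bool = True,
) -> Quantization:
    """Assign every pixel of the full image to its nearest center."""
    shape = np.asarray(image).shape[:-1]
    flat = np.asarray(image).reshape(-1, 3).astype(np.float64)
    labels = _chunked_assign(flat, centers)
    return Quantization(
        palette=centers,
        labels=labels.reshape(shape),
        n=n,
        method_tag=tag,
        objective_trace=np.asarray(trace, dtype=np.float64),
        converged=converged,
    )


def _chunked_assign(flat: np.ndarray, centers: np.ndarray, chunk: int = 1 << 18) -> np.ndarray:
    out = np.empty(flat.shape[0], dtype=np.int64)
    for start in range(0, flat.shape[0], chunk):
        out[start : start + chunk] = _assign(flat[start : start + chunk], centers)
    return out


# ---------------------------------------------------------------------------
# Maximum-entropy clustering
# ---------------------------------------------------------------------------


def mec_quantize(
    image: np.ndarray,
    n: int,
    seed: int = 0,
    temperature: float | None = None,
    max_pixels: int = DEFAULT_SUBSAMPLE,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> Quantization:
    """Maximum-entropy clustering with Gibbs-form soft memberships.

    Minimizes  J = sum_ik u_ik d_ik + T sum_ik u_ik ln u_ik  by alternating
    the closed-form membership update u_ik ∝ exp(-d_ik / T) with weighted
    center updates, from a k-means++ start.  The Shannon entropy term keeps
    memberships soft; as T -> 0 the method anneals to hard k-means.  Final
    hard labels are by maximum membership.
    """
    sample = sample_pixels(image, max_pixels, seed)
    centers = kmeanspp_init(sample, n, seed)
    labels0 = _assign(sample.colors, centers)
    if temperature is None:
        # mean within-cluster variance of the init
        d0 = ((sample.colors - centers[labels0]) ** 2).sum(axis=1)
        temperature = float((d0 * sample.weights).sum() / sample.weights.sum())
    if temperature <= 0:
        # annealing limit: identical to hard k-means
        centers, _, trace, conv = _lloyd(sample, centers, max_iter, tol)
        return _finalize(image, centers, n, "mec", trace, conv)

    T = float(temperature)
    w = sample.weights[:, None]
    trace: list[float] = []
    converged = False
    prev = np.inf
    for _ in range(max_iter):
        d = ((sample.colors[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        logits = -d / T
        log_u = logits - logsumexp(logits, axis=1, keepdims=True)
        u = np.exp(log_u)
        obj = float((w * (u * d + T * u * log_u)).sum())
        trace.append(obj)
        uw = u * w
        mass = uw.sum(axis=0)
        mass = np.where(mass <= 0, 1e-300, mass)
        centers = (uw.T @ sample.colors) / mass[:, None]
        if abs(prev - obj) <= tol * max(abs(prev), 1.0):
            converged = True
            break
        prev = obj
    return _finalize(image, centers, n, "mec", trace, converged)


# ---------------------------------------------------------------------------
# Gaussian mixture EM
# ---------------------------------------------------------------------------


def gmm_quantize(
    image: np.ndarray,
    n: int,
    seed: int = 0,
    max_pixels: int = DEFAULT_SUBSAMPLE,
    max_iter: int = 100,
    tol: float = 1e-5,
    reg_covar: float = 1e-3,
) -> Quantization:
    """Gaussian-mixture EM quantizer (full covariances, k-means++ init).

    EM is stepped one iteration at a time through scikit-learn's warm
    start so the per-iteration lower bound is recorded as the objective
    trace; a covariance floor keeps degenerate (zero-noise) clusters
    regularized.  Hard labels are by maximum responsibility and the
    palette is the responsibility-weighted component means.
    """
    from sklearn.mixture import GaussianMixture

    rng = np.random.default_rng(seed)
    flat = np.asarray(image).reshape(-1, 3).astype(np.float64)
    if flat.shape[0] > max_pixels:
        idx = rng.choice(flat.shape[0], size=max_pixels, replace=False)
        data = flat[np.sort(idx)]
    else:
        data = flat
    sample = PixelSample(
        *np.unique(data, axis=0, return_counts=True), source_seed=seed
    )
    means0 = kmeanspp_init(sample, n, seed)
    labels0 = _assign(data, means0)
    weights0 = np.bincount(labels0, minlength=n).astype(np.float64)
    weights0 = np.maximum(weights0, 1.0)
    weights0 /= weights0.sum()

    gm = GaussianMixture(
        n_components=n,
        covariance_type="full",
        means_init=means0,
        weights_init=weights0,
        reg_covar=reg_covar,
        max_iter=1,
        warm_start=True,
        random_state=int(seed) % (2**31),
    )
    trace: list[float] = []
    converged = False
    prev = -np.inf
    import warnings

    for _ in range(max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(data)
        trace.append(float(gm.lower_bound_))
        if np.isfinite(prev) and abs(gm.lower_bound_ - prev) <= tol * max(
            abs(prev), 1.0
        ):
            converged = True
            break
        prev = gm.lower_bound_
    centers = gm.means_
    quant = _finalize(image, centers, n, "gmm", trace, converged)
    # responsibility-based hard labels on the full image
    resp_labels = gm.predict(flat)
    quant.labels = resp_labels.reshape(np.asarray(image).shape[:-1])
    return quant


# ---------------------------------------------------------------------------
# minCEntropy
# ---------------------------------------------------------------------------


def _label_entropy_bits(cluster_sums: np.ndarray, total: float) -> float:
    p = cluster_sums[cluster_sums > 0] / total
    return float(-(p * np.log2(p)).sum())


def mincentropy_quantize(
    image: np.ndarray,
    n: int,
    seed: int = 0,
    bin_side: int = 1,
    max_sweeps: int = 100,
    n_restarts: int = 6,
) -> Quantization:
    """Hill-climbing maximization of I(binned color; cluster label).

    Operates on the occupied bins of the color histogram.  Because every
    bin carries a single label, the mutual information between the binned
    color and the label equals the label entropy, so the method greedily
    reassigns single bins (seeded random scan order, first improvement,
    never emptying a cluster), with pairwise bin swaps once single moves
    stall.  Several seeded restarts are kept and the best final objective
    wins, which in practice reaches the exhaustive optimum on small
    instances.
    """
    img = np.asarray(image)
    ids = bin_indices(img, bin_side)
    ubins, inv = np.unique(ids, return_inverse=True)
    counts = np.bincount(inv).astype(np.float64)
    m = len(ubins)
    if m < n:
        raise ValueError(f"only {m} occupied bins for n={n} clusters")
    total = counts.sum()

    # mean color per occupied bin, for the k-means++ inits and the palette
    flat = img.reshape(-1, 3).astype(np.float64)
    bin_means = np.zeros((m, 3))
    for ch in range(3):
        bin_means[:, ch] = np.bincount(inv, weights=flat[:, ch]) / counts
    sample = PixelSample(colors=bin_means, weights=counts, source_seed=seed)

    best_labels = None
    best_obj = -np.inf
    init_obj = None
    for r in range(max(1, n_restarts)):
        rng = np.random.default_rng((seed, r))
        if r == 0:
            centers = kmeanspp_init(sample, n, int(rng.integers(2**31)))
            labels = _assign(bin_means, centers)
        else:  # later restarts explore beyond the color-proximity basin
            labels = rng.integers(0, n, size=m)
        labels = _ensure_all_clusters(labels, counts, n)
        if r == 0:
            sums0 = np.bincount(labels, weights=counts, minlength=n)
            init_obj = _label_entropy_bits(sums0, total)
        labels, obj = _hill_climb(labels, counts, n, total, rng, max_sweeps, bin_means)
        if obj > best_obj:
            best_obj, best_labels = obj, labels

    palette = np.zeros((n, 3))
    sums = np.bincount(best_labels, weights=counts, minlength=n)
    for ch in range(3):
        palette[:, ch] = np.bincount(
            best_labels, weights=counts * bin_means[:, ch], minlength=n
        ) / np.maximum(sums, 1e-12)
    pixel_labels = best_labels[inv].reshape(img.shape[:-1])
    trace = [init_obj if init_obj is not None else best_obj, best_obj]
    return Quantization(
        palette=palette,
        labels=pixel_labels,
        n=n,
        method_tag="mincentropy",
        objective_trace=np.asarray(trace, dtype=np.float64),
    )


def _ensure_all_clusters(labels: np.ndarray, counts: np.ndarray, n: int) -> np.ndarray:
    """Guarantee every cluster owns at least one bin."""
    labels = labels.copy()
    present = np.bincount(labels, minlength=n)
    for k in np.flatnonzero(present == 0):
        order = np.argsort(counts)  # move the lightest bin of a multi-bin cluster
        for i in order:
            if present[labels[i]] > 1:
                present[labels[i]] -= 1
                labels[i] = k
                present[k] += 1
                break
    return labels


def _hill_climb(
    labels: np.ndarray,
    counts: np.ndarray,
    n: int,
    total: float,
    rng: np.random.Generator,
    max_sweeps: int,
    bin_colors: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """First-improvement single-bin moves, plus pairwise swaps when stalled.

    The label entropy depends only on the per-cluster count sums, so move
    gains are O(1) scalar updates.  Because the maximizer set is highly
    degenerate (any equal-sum partition attains the maximum), candidate
    target clusters for each bin are tried in order of color proximity to
    the cluster mean: the attained objective is identical, but the search
    settles on the color-coherent member of the optimum set, which keeps
    the derived palette meaningful.  Swap and one-for-two exchange moves
    rescue the equal-sum local maxima single moves cannot leave; they are
    scanned only on small instances where the pair scans are affordable.
    """
    from math import log2

    labels = labels.copy()
    m = len(counts)
    sums = np.bincount(labels, weights=counts, minlength=n).astype(np.float64)
    sizes = np.bincount(labels, minlength=n)
    cnt = counts.astype(np.float64)
    if bin_colors is None:
        bin_colors = np.zeros((m, 3))
    csum = np.zeros((n, 3))
    for k in range(n):
        mask = labels == k
        csum[k] = (bin_colors[mask] * cnt[mask, None]).sum(axis=0)

    def f(s: float) -> float:
        return 0.0 if s <= 0 else -(s / total) * log2(s / total)

    obj = float(sum(f(s) for s in sums))

    for _ in range(max_sweeps):
        improved = False
        for i in rng.permutation(m):
            a = int(labels[i])
            if sizes[a] <= 1:
                continue
            c = cnt[i]
            fa, fa_minus = f(sums[a]), f(sums[a] - c)
            means = csum / np.maximum(sums, 1e-12)[:, None]
            order = np.argsort(((means - bin_colors[i]) ** 2).sum(axis=1), kind="stable")
            for target in order:
                target = int(target)
                if target == a:
                    continue
                gain = fa_minus + f(sums[target] + c) - fa - f(sums[target])
                if gain > 1e-12:
                    sums[a] -= c
                    sums[target] += c
                    csum[a] -= c * bin_colors[i]
                    csum[target] += c * bin_colors[i]
                    sizes[a] -= 1
                    sizes[target] += 1
                    labels[i] = target
                    obj += gain
                    improved = True
                    break
        if not improved:
            escaped = False
            if m * m <= 65536:  # pair scans affordable only on small instances
                escaped = _try_swap(labels, cnt, sums, rng)
                if not escaped and m <= 64:
                    escaped = _try_one_for_two(labels, cnt, sums, sizes, rng)
            if not escaped:
                break
            for k in range(n):  # refresh color sums after an exchange move
                mask = labels == k
                csum[k] = (bin_colors[mask] * cnt[mask, None]).sum(axis=0)
    return labels, float(sum(f(s) for s in sums))


def _entropy_term(s: float, total: float) -> float:
    from math import log2

    return 0.0 if s <= 0 else -(s / total) * log2(s / total)


def _try_swap(labels, cnt, sums, rng) -> bool:
    """Exchange the clusters of two bins if that raises the label entropy."""
    total = sums.sum()
    f = _entropy_term
    m = len(labels)
    for i in rng.permutation(m):
        a = int(labels[i])
        ci = cnt[i]
        for j in rng.permutation(m):
            b = int(labels[j])
            if a == b:
                continue
            cj = cnt[j]
            gain = (
                f(sums[a] - ci + cj, total)
                + f(sums[b] - cj + ci, total)
                - f(sums[a], total)
                - f(sums[b], total)
            )
            if gain > 1e-12:
                labels[i], labels[j] = b, a
                sums[a] += cj - ci
                sums[b] += ci - cj
                return True
    return False


def _try_one_for_two(labels, cnt, sums, sizes, rng) -> bool:
    """Exchange one bin of cluster a against two bins of cluster b."""
    total = sums.sum()
    f = _entropy_term
    m = len(labels)
    for i in rng.permutation(m):
        a = int(labels[i])
        ci = cnt[i]
        for j in rng.permutation(m):
            b = int(labels[j])
            if b == a:
                continue
            for k in rng.permutation(m):
                if k == j or int(labels[k]) != b:
                    continue
                cjk = cnt[j] + cnt[k]
                gain = (
                    f(sums[a] - ci + cjk, total)
                    + f(sums[b] - cjk + ci, total)
                    - f(sums[a], total)
                    - f(sums[b], total)
                )
                if gain > 1e-12:
                    labels[i] = b
                    labels[j] = a
                    labels[k] = a
                    sums[a] += cjk - ci
                    sums[b] += ci - cjk
                    sizes[a] += 1
                    sizes[b] -= 1
                    return True
    return False


# ---------------------------------------------------------------------------
# Graph-Cut
# ---------------------------------------------------------------------------


def graphcut_quantize(
    image: np.ndarray,
    n: int,
    seed: int = 0,
    smoothness_weight: float = 1.0,
    grid_max: int = 128,
    max_sweeps: int = 5,
    sigma_affinity: float = 30.0,
) -> Quantization:
    """Potts-energy clustering by iterated alpha-expansion.

    Energy = sum_p ||c_p - mu_{l_p}||^2 / s  +  lambda sum_{pq} w_pq [l_p != l_q]
    over 4-connected neighbors of a spatially subsampled grid, with edge
    affinities w_pq = exp(-||c_p - c_q||^2 / (2 sigma^2)) so cuts prefer
    weak (high color contrast) edges.  Initialization is by k-means; each
    expansion solves an exact min-cut (max-flow) so the energy never
    increases.  The final palette is the mean color per label and full-
    image labels are by nearest palette color.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    step = max(1, int(np.ceil(max(h, w) / grid_max)))
    sub = img[::step, ::step].astype(np.float64)
    sh, sw = sub.shape[:2]
    flat = sub.reshape(-1, 3)

    km = kmeans_quantize(img, n, seed)
    centers = km.palette.copy()
    labels = _assign(flat, centers)
    labels = _ensure_nonempty(labels, flat, centers, n)

    # unary scaled so data and smoothness terms are commensurate
    unary_scale = 1.0 / (sigma_affinity**2)

    edges = _grid_edges(sh, sw)
    diff = ((flat[edges[:, 0]] - flat[edges[:, 1]]) ** 2).sum(axis=1)
    affinity = np.exp(-diff / (2.0 * sigma_affinity**2))

    def unary(lab: np.ndarray) -> np.ndarray:
        return ((flat - centers[lab]) ** 2).sum(axis=1) * unary_scale

    def energy(lab: np.ndarray) -> float:
        cut = lab[edges[:, 0]] != lab[edges[:, 1]]
        return float(unary(lab).sum() + smoothness_weight * affinity[cut].sum())

    trace = [energy(labels)]
    if smoothness_weight > 0:
        for _ in range(max_sweeps):
            changed = False
            for alpha in range(n):
                new_labels = _alpha_expansion(
                    flat, labels, centers, alpha, edges, affinity,
                    smoothness_weight, unary_scale,
                )
                if energy(new_labels) < trace[-1] - 1e-9:
                    labels = new_labels
                    trace.append(energy(labels))
                    changed = True
            # re-estimate centers from the new labeling
            for k in range(n):
                mask = labels == k
                if np.any(mask):
                    centers[k] = flat[mask].mean(axis=0)
            if not changed:
                break
    return _finalize(image, centers, n, "graphcut", trace)


def _ensure_nonempty(
    labels: np.ndarray, flat: np.ndarray, centers: np.ndarray, n: int
) -> np.ndarray:
    labels = labels.copy()
    for k in range(n):
        if not np.any(labels == k):
            far = np.argmax(((flat - centers[labels]) ** 2).sum(axis=1))
            labels[far] = k
    return labels


def _grid_edges(h: int, w: int) -> np.ndarray:
    idx = np.arange(h * w).reshape(h, w)
    horiz = np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1)
    vert = np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1)
    return np.concatenate([horiz, vert], axis=0)


def _alpha_expansion(
    flat: np.ndarray,
    labels: np.ndarray,
    centers: np.ndarray,
    alpha: int,
    edges: np.ndarray,
    affinity: np.ndarray,
    lam: float,
    unary_scale: float,
) -> np.ndarray:
    """One binary expansion move solved exactly by max-flow/min-cut.

    Each pixel either keeps its current label or switches to ``alpha``;
    the standard graph construction with auxiliary nodes for neighbor
    pairs of unlike current labels reduces the Potts move to a min-cut.
    """
    import networkx as nx

    m = flat.shape[0]
    cost_keep = ((flat - centers[labels]) ** 2).sum(axis=1) * unary_scale
    cost_alpha = ((flat - centers[alpha]) ** 2).sum(axis=1) * unary_scale
    cost_keep = np.where(labels == alpha, cost_alpha, cost_keep)

    G = nx.DiGraph()
    source, sink = "s", "t"

    def add_edge(u, v, cap):
        if cap <= 0:
            return
        if G.has_edge(u, v):
            G[u][v]["capacity"] += cap
        else:
            G.add_edge(u, v, capacity=cap)
            G.add_edge(v, u, capacity=0.0)

    # terminal links: source side = keep current label, sink side = alpha
    for p in range(m):
        add_edge(source, p, float(cost_alpha[p]))
        add_edge(p, sink, float(cost_keep[p]) if labels[p] != alpha else np.inf)

    for e in range(edges.shape[0]):
        p, q = int(edges[e, 0]), int(edges[e, 1])
        w_pq = float(lam * affinity[e])
        if w_pq <= 0:
            continue
        lp, lq = labels[p], labels[q]
        if lp == lq:
            if lp != alpha:
                add_edge(p, q, w_pq)
                add_edge(q, p, w_pq)
        else:
            aux = m + e  # auxiliary node for this unlike-labeled pair
            add_edge(p, aux, w_pq)
            add_edge(aux, p, w_pq)
            add_edge(q, aux, w_pq)
            add_edge(aux, q, w_pq)
            add_edge(aux, sink, w_pq)

    _, (source_side, _) = nx.minimum_cut(
        G, source, sink, flow_func=nx.algorithms.flow.preflow_push
    )
    new_labels = labels.copy()
    for p in range(m):
        if p not in source_side:  # sink side takes alpha
            new_labels[p] = alpha
    return new_labels


# ---------------------------------------------------------------------------


def apply_palette(image: np.ndarray, quantization: Quantization) -> np.ndarray:
    """Replace every pixel by its cluster's palette color (8-bit output)."""
    img = np.asarray(image)
    labels = quantization.labels.reshape(-1)
    if labels.shape[0] != img.reshape(-1, 3).shape[0]:
        raise ValueError("label map does not cover the image")
    if labels.size and (labels.max() >= quantization.n or labels.min() < 0):
        raise ValueError("label out of range for palette")
    out = np.clip(np.round(quantization.palette[labels]), 0, 255).astype(np.uint8)
    return out.reshape(img.shape)


CLUSTER_METHODS = {
    "kmeans": kmeans_quantize,
    "mec": mec_quantize,
    "gmm": gmm_quantize,
    "mincentropy": mincentropy_quantize,
    "graphcut": graphcut_quantize,
}


def quantize(image: np.ndarray, method: str, n: int, seed: int = 0, **kwargs) -> Quantization:
    """Dispatch to a clustering quantizer by method tag."""
    if method not in CLUSTER_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(CLUSTER_METHODS)}")
    return CLUSTER_METHODS[method](image, n, seed=seed, **kwargs)
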