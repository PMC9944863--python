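"""Objective estimation of the number of relevant colors.

Three methods select a cluster count n for an image without observer
input: a Calinski-Harabasz (variance-ratio criterion) scan, a
Davies-Bouldin scan, and an adaptive k-means that spawns clusters without
a predetermined n.  The two index scans cluster a pixel sample by k-means
at every candidate n and pick the argmax (VRC) or argmin (Davies-Bouldin)
of the index curve; the curves are kept in the result so summaries across
an image set can be recomputed without re-clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

from .quantize import (
    PixelSample,
    Quantization,
    _assign,
    _chunked_assign,
    _lloyd,
    kmeanspp_init,
    sample_pixels,
)

__all__ = [
    "ClusterCountResult",
    "calinski_harabasz_scan",
    "davies_bouldin_scan",
    "adaptive_kmeans",
]

ADAPTIVE_HARD_CAP = 1024


@dataclass
class ClusterCountResult:
    method_tag: str
    n_opt: int
    index_curve: np.ndarray  # index value per scanned n (NaN where undefined)
    n_range: tuple[int, int]
    clamped: bool = False  # n_max clamped to the number of distinct colors

    def __post_init__(self) -> None:
        if not (self.n_range[0] <= self.n_opt <= self.n_range[1]):
            raise ValueError("selected n lies outside the scanned range")


def _expand(sample: PixelSample, cap: int = 50_000) -> np.ndarray:
    """Expand weighted distinct colors to points for the sklearn indices."""
    reps = np.round(sample.weights).astype(np.int64)
    if reps.sum() > cap:
        reps = np.maximum(1, (reps * cap / reps.sum()).astype(np.int64))
    return np.repeat(sample.colors, reps, axis=0)


def _scan(
    sample: PixelSample, n_min: int, n_max: int, seed: int, score, pick
) -> tuple[int, np.ndarray, bool]:
    if not (2 <= n_min <= n_max):
        raise ValueError(f"need 2 <= n_min <= n_max, got [{n_min}, {n_max}]")
    m = sample.colors.shape[0]
    clamped = False
    if n_max >= m:
        n_max = max(n_min, m - 1)
        clamped = True
    points = _expand(sample)
    curve = np.full(n_max - n_min + 1, np.nan)
    for i, n in enumerate(range(n_min, n_max + 1)):
        # per-n seed stream so curves are reproducible pointwise
        centers = kmeanspp_init(sample, n, seed=(seed, n))
        centers, labels, _, _ = _lloyd(sample, centers)
        point_labels = _assign(points, centers)
        if len(np.unique(point_labels)) < 2:
            continue
        curve[i] = score(points, point_labels)
    n_opt = n_min + int(pick(curve))
    return n_opt, curve, clamped


def calinski_harabasz_scan(
    sample: PixelSample, n_min: int = 2, n_max: int = 40, seed: int = 0
) -> ClusterCountResult:
    """Pick n maximizing the variance-ratio criterion over a k-means scan.

    VRC(n) = [B / (n - 1)] / [W / (N - n)] with B and W the between- and
    within-cluster sums of squared distances.
    """
    n_opt, curve, clamped = _scan(
        sample, n_min, n_max, seed, calinski_harabasz_score, np.nanargmax
    )
    return ClusterCountResult(
        method_tag=f"calinski_harabasz_{n_max}",
        n_opt=n_opt,
        index_curve=curve,
        n_range=(n_min, n_min + len(curve) - 1),
        clamped=clamped,
    )


def davies_bouldin_scan(
    sample: PixelSample, n_min: int = 2, n_max: int = 80, seed: int = 0
) -> ClusterCountResult:
    """Pick n minimizing the Davies-Bouldin within/between distance ratio."""
    n_opt, curve, clamped = _scan(
        sample, n_min, n_max, seed, davies_bouldin_score, np.nanargmin
    )
    return ClusterCountResult(
        method_tag=f"davies_bouldin_{n_max}",
        n_opt=n_opt,
        index_curve=curve,
        n_range=(n_min, n_min + len(curve) - 1),
        clamped=clamped,
    )


def adaptive_kmeans(
    image: np.ndarray,
    distance_threshold: float = 32.0,
    max_pixels: int = 100_000,
    seed: int = 0,
    max_iter: int = 100,
) -> tuple[ClusterCountResult, Quantization]:
    """k-means without a predetermined n: distant pixels spawn new centers.

    The first center is the mean of the RGB image planes.  Any pixel
    farther than ``distance_threshold`` from every current center spawns a
    new center at the most distant such pixel; centers are then updated by
    Lloyd steps until assignments stabilize.
    """
    if distance_threshold <= 0:
        raise ValueError("distance_threshold must be positive")
    sample = sample_pixels(image, max_pixels, seed)
    colors, weights = sample.colors, sample.weights
    centers = [(colors * weights[:, None]).sum(axis=0) / weights.sum()]

    for _ in range(max_iter):
        # spawn a center at the most distant unexplained pixel until every
        # pixel is within the threshold of some center
        c = np.array(centers)
        nearest = np.sqrt(((colors[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
        while np.any(nearest > distance_threshold):
            if len(centers) >= ADAPTIVE_HARD_CAP:
                raise RuntimeError(
                    f"adaptive k-means exceeded {ADAPTIVE_HARD_CAP} clusters; "
                    "increase distance_threshold"
                )
            new_center = colors[int(np.argmax(nearest))]
            centers.append(new_center)
            nearest = np.minimum(
                nearest, np.sqrt(((colors - new_center) ** 2).sum(axis=1))
            )
        c = np.array(centers)
        d = np.sqrt(((colors[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))
        labels = np.argmin(d, axis=1)
        keep = np.unique(labels)
        new = np.array(
            [
                (colors[labels == k] * weights[labels == k, None]).sum(axis=0)
                / weights[labels == k].sum()
                for k in keep
            ]
        )
        stable = len(keep) == len(centers) and np.allclose(new, c[keep], atol=1e-9)
        centers = list(new)  # empty clusters dropped
        if stable:
            break

    c = np.array(centers)
    n = len(centers)
    img = np.asarray(image)
    flat = img.reshape(-1, 3).astype(np.float64)
    labels = _chunked_assign(flat, c)
    quant = Quantization(
        palette=c, labels=labels.reshape(img.shape[:-1]), n=n, method_tag="adaptive_kmeans"
    )
    result = ClusterCountResult(
        method_tag="adaptive_kmeans", n_opt=n, index_curve=np.array([float(n)]),
        n_range=(1, max(n, 1)),
    )
    return result, quant
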