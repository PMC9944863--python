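"""Entropy and mutual-information estimation for quantized images.

A pixel drawn at random from an image is a trivariate discrete random
variable A = (R, G, B); its quantized representation A_q is the cluster
label of that pixel.  Entropies are estimated from histograms over a
binned color space, either by the naive plug-in estimator or by the
Grassberger bias-corrected estimator, and combined into the mutual
information

    I(A; A_q) = H(A) + H(A_q) - H(A, A_q)        (bits)

The efficiency of a quantization method is the ratio eta = I / I_ref of
its mutual information to that of a reference method on the same image at
the same number of colors n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma

__all__ = [
    "ColorHistogram",
    "JointHistogram",
    "InfoResult",
    "EfficiencyRecord",
    "bin_colors",
    "bin_indices",
    "naive_entropy",
    "grassberger_entropy",
    "entropy_from_counts",
    "mutual_information",
    "image_quantization_mi",
    "efficiency",
]

_LN2 = np.log(2.0)


@dataclass
class ColorHistogram:
    """Counts over occupied bins of a binned color space."""

    counts: np.ndarray  # positive ints, one entry per occupied bin
    total: int
    bin_side: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.size and self.counts.min() < 1:
            raise ValueError("occupied bins must have counts >= 1")
        if self.total != int(self.counts.sum()):
            raise ValueError("total must equal the sum of counts")


@dataclass
class JointHistogram:
    """Sparse joint counts over (original-color-bin, quantized-label) pairs."""

    row_index: np.ndarray  # color-bin id per occupied cell
    col_index: np.ndarray  # label per occupied cell
    counts: np.ndarray
    n_labels: int = 0

    def __post_init__(self) -> None:
        if not (len(self.row_index) == len(self.col_index) == len(self.counts)):
            raise ValueError("row_index, col_index and counts must be parallel arrays")
        if self.n_labels == 0 and len(self.col_index):
            self.n_labels = int(np.max(self.col_index)) + 1

    @property
    def total(self) -> int:
        return int(np.sum(self.counts))

    def marginal_rows(self) -> np.ndarray:
        """Counts of the original-color marginal."""
        _, inv = np.unique(self.row_index, return_inverse=True)
        return np.bincount(inv, weights=self.counts).astype(np.int64)

    def marginal_cols(self) -> np.ndarray:
        """Counts of the quantized-label marginal."""
        return np.bincount(
            np.asarray(self.col_index), weights=self.counts, minlength=self.n_labels
        ).astype(np.int64)

    @classmethod
    def from_dense(cls, table: np.ndarray) -> "JointHistogram":
        table = np.asarray(table)
        rows, cols = np.nonzero(table)
        return cls(rows, cols, table[rows, cols], n_labels=table.shape[1])


@dataclass
class InfoResult:
    """Entropies and mutual information of an (image, quantization) pair, in bits."""

    H_original: float
    H_quantized: float
    H_joint: float
    estimator_tag: str

    @property
    def I(self) -> float:
        return self.H_original + self.H_quantized - self.H_joint


@dataclass
class EfficiencyRecord:
    I: float
    I_ref: float
    image_id: str = ""
    n: int = 0
    method_tag: str = ""

    @property
    def eta(self) -> float:
        return self.I / self.I_ref


def bin_indices(image: np.ndarray, bin_side: int) -> np.ndarray:
    """Flat bin id per pixel: each channel floor-divided by ``bin_side``.

    Ids encode the (R, G, B) bin cube on a fixed grid so the same color
    always maps to the same id regardless of image content.
    """
    if bin_side < 1:
        raise ValueError(f"bin_side must be >= 1, got {bin_side}")
    arr = np.asarray(image)
    if arr.shape[-1] != 3:
        raise ValueError(f"expected 3 channels, got shape {arr.shape}")
    cubes = arr.reshape(-1, 3).astype(np.int64) // bin_side
    per_axis = (255 // bin_side) + 1
    return (cubes[:, 0] * per_axis + cubes[:, 1]) * per_axis + cubes[:, 2]


def bin_colors(image: np.ndarray, bin_side: int) -> ColorHistogram:
    """Histogram of pixel colors over cubic bins of side ``bin_side``."""
    ids = bin_indices(image, bin_side)
    _, counts = np.unique(ids, return_counts=True)
    return ColorHistogram(counts=counts, total=int(counts.sum()), bin_side=bin_side)


def _counts_vector(hist) -> np.ndarray:
    counts = hist.counts if isinstance(hist, ColorHistogram) else np.asarray(hist)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("empty histogram has no defined entropy")
    return counts.astype(np.float64)


def naive_entropy(hist) -> float:
    """Plug-in entropy -sum (c/N) log2 (c/N) in bits."""
    counts = _counts_vector(hist)
    total = counts.sum()
    p = counts / total
    return float(-(p * np.log2(p)).sum())


def _grassberger_g(counts: np.ndarray) -> np.ndarray:
    # G(n) = psi(n) + (1/2)(-1)^n [psi((n+1)/2) - psi(n/2)]
    sign = np.where(counts % 2 == 0, 1.0, -1.0)
    return digamma(counts) + 0.5 * sign * (digamma((counts + 1) / 2.0) - digamma(counts / 2.0))


def grassberger_entropy(hist) -> float:
    """Grassberger (2003) bias-corrected entropy estimate, in bits.

    H_hat = ln N - (1/N) sum_i n_i G(n_i), converted from nats, where G
    applies a digamma-based per-count correction that removes most of the
    downward bias of the plug-in estimator at small sample sizes.
    """
    counts = _counts_vector(hist)
    total = counts.sum()
    h_nats = np.log(total) - float((counts * _grassberger_g(counts)).sum()) / total
    return h_nats / _LN2


def entropy_from_counts(counts, estimator: str = "naive") -> float:
    if estimator == "naive":
        return naive_entropy(counts)
    if estimator == "grassberger":
        return grassberger_entropy(counts)
    raise ValueError(f"unknown estimator {estimator!r}")


def mutual_information(joint: JointHistogram, estimator: str = "naive") -> InfoResult:
    """Mutual information from a joint histogram by the three-entropy identity.

    The chosen estimator is applied to both marginals and to the joint
    alike.  Under the bias-corrected estimator the result can be slightly
    negative; it is reported as-is, not clipped.
    """
    if len(joint.counts) == 0:
        raise ValueError("empty joint histogram")
    h1 = entropy_from_counts(joint.marginal_rows(), estimator)
    h2 = entropy_from_counts(joint.marginal_cols(), estimator)
    h12 = entropy_from_counts(joint.counts, estimator)
    return InfoResult(H_original=h1, H_quantized=h2, H_joint=h12, estimator_tag=estimator)


def joint_histogram(
    image: np.ndarray, labels: np.ndarray, bin_side: int = 8
) -> JointHistogram:
    """Joint counts of (binned original color, quantized label) over all pixels."""
    ids = bin_indices(image, bin_side)
    labels = getattr(labels, "labels", labels)  # accept a Quantization
    lab = np.asarray(labels).reshape(-1)
    if lab.shape[0] != ids.shape[0]:
        raise ValueError(
            f"label map has {lab.shape[0]} entries for {ids.shape[0]} pixels"
        )
    n_labels = int(lab.max()) + 1 if lab.size else 0
    pair = ids * np.int64(n_labels) + lab
    upair, counts = np.unique(pair, return_counts=True)
    return JointHistogram(
        row_index=upair // n_labels,
        col_index=(upair % n_labels).astype(np.int64),
        counts=counts,
        n_labels=n_labels,
    )


def image_quantization_mi(
    image: np.ndarray,
    labels: np.ndarray,
    bin_side: int = 8,
    estimator: str = "naive",
) -> InfoResult:
    """MI between an image's binned colors and its quantization labels."""
    return mutual_information(joint_histogram(image, labels, bin_side), estimator)


def efficiency(
    I: float, I_ref: float, image_id: str = "", n: int = 0, method_tag: str = ""
) -> EfficiencyRecord:
    """Efficiency eta = I / I_ref of a method against the reference method."""
    if I_ref <= 0:
        raise ValueError(f"reference information must be positive, got {I_ref}")
    return EfficiencyRecord(I=I, I_ref=I_ref, image_id=image_id, n=n, method_tag=method_tag)
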