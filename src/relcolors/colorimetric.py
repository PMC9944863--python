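"""Colorimetric relevant-color quantizer.

CIELAB space is partitioned into cubic cells of fixed side (a multiple of
the smallest discriminable color step).  A cell is designated *relevant*
when it holds enough of the image's pixels and its mean color lies inside
a plausible lightness/chroma range; every pixel then takes the average
color of its own cell if relevant, otherwise of the nearest relevant cell.
Unlike the general clustering methods, the number of relevant colors n is
determined automatically by the designation rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorspace import srgb_to_lab
from .quantize import Quantization

__all__ = [
    "ColorimetricConfig",
    "LabCellGrid",
    "build_cell_grid",
    "designate_relevant",
    "colorimetric_quantize",
]

# Fixed cell-grid origin so grids are reproducible across images.
_GRID_ORIGIN = np.array([0.0, -128.0, -128.0])


@dataclass(frozen=True)
class ColorimetricConfig:
    """Thresholds of the relevance rule (all in CIELAB units / fractions).

    A cell is relevant iff its pixel share is at least ``min_fraction``,
    its mean L* lies in [lightness_min, lightness_max], and its mean chroma
    is at least ``min_chroma`` — except that near-neutral cells are kept
    when they are strongly occupied (share >= neutral_exemption_factor *
    min_fraction), since grays and browns dominate many paintings.
    """

    cell_side: float = 10.0
    min_fraction: float = 0.001
    lightness_min: float = 5.0
    lightness_max: float = 95.0
    min_chroma: float = 5.0
    neutral_exemption_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.cell_side <= 0:
            raise ValueError(f"cell_side must be positive, got {self.cell_side}")


@dataclass
class LabCellGrid:
    """Occupied CIELAB cells with counts, mean colors and relevance flags."""

    cell_ids: np.ndarray  # (m, 3) integer cell coordinates
    counts: np.ndarray  # (m,)
    mean_lab: np.ndarray  # (m, 3)
    mean_rgb: np.ndarray  # (m, 3) mean of member pixels in RGB
    cell_side: float
    total: int
    relevant: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    relaxed: bool = False  # no cell passed; fell back to the most occupied

    @property
    def mean_chroma(self) -> np.ndarray:
        return np.hypot(self.mean_lab[:, 1], self.mean_lab[:, 2])


def build_cell_grid(
    lab_values: np.ndarray, cell_side: float, rgb_values: np.ndarray | None = None
) -> LabCellGrid:
    """Assign pixels to cubic CIELAB cells and accumulate per-cell statistics.

    ``lab_values`` is (..., 3); ``rgb_values``, when given, must be the
    matching 8-bit RGB pixels so palette averages can be taken in RGB.
    """
    if cell_side <= 0:
        raise ValueError(f"cell_side must be positive, got {cell_side}")
    lab = np.asarray(lab_values, dtype=np.float64).reshape(-1, 3)
    cells = np.floor((lab - _GRID_ORIGIN) / cell_side).astype(np.int64)
    uniq, inv, counts = np.unique(cells, axis=0, return_inverse=True, return_counts=True)
    mean_lab = np.zeros((len(uniq), 3))
    for ch in range(3):
        mean_lab[:, ch] = np.bincount(inv, weights=lab[:, ch]) / counts
    if rgb_values is not None:
        rgb = np.asarray(rgb_values, dtype=np.float64).reshape(-1, 3)
        mean_rgb = np.zeros((len(uniq), 3))
        for ch in range(3):
            mean_rgb[:, ch] = np.bincount(inv, weights=rgb[:, ch]) / counts
    else:
        mean_rgb = mean_lab.copy()
    return LabCellGrid(
        cell_ids=uniq,
        counts=counts,
        mean_lab=mean_lab,
        mean_rgb=mean_rgb,
        cell_side=float(cell_side),
        total=int(counts.sum()),
    )


def designate_relevant(grid: LabCellGrid, config: ColorimetricConfig) -> LabCellGrid:
    """Flag cells as relevant by occupancy and lightness/chroma criteria."""
    share = grid.counts / grid.total
    L = grid.mean_lab[:, 0]
    chroma = grid.mean_chroma
    chromatic_ok = chroma >= config.min_chroma
    neutral_ok = (~chromatic_ok) & (
        share >= config.neutral_exemption_factor * config.min_fraction
    )
    relevant = (
        (share >= config.min_fraction)
        & (L >= config.lightness_min)
        & (L <= config.lightness_max)
        & (chromatic_ok | neutral_ok)
    )
    relaxed = False
    if not np.any(relevant):
        relevant = np.zeros(len(grid.counts), dtype=bool)
        relevant[int(np.argmax(grid.counts))] = True
        relaxed = True
    grid.relevant = relevant
    grid.relaxed = relaxed
    return grid


def colorimetric_quantize(
    image: np.ndarray, config: ColorimetricConfig | None = None
) -> Quantization:
    """Quantize an image by its relevant CIELAB cells; n is automatic.

    Pixels in relevant cells take their cell's average color; pixels in
    non-relevant cells take the nearest relevant-cell average (Euclidean
    distance between cell means in CIELAB, ties broken toward the lowest
    cell index).
    """
    cfg = config if config is not None else ColorimetricConfig()
    img = np.asarray(image)
    lab = srgb_to_lab(img).values
    grid = build_cell_grid(lab, cfg.cell_side, rgb_values=img)
    grid = designate_relevant(grid, cfg)

    rel_idx = np.flatnonzero(grid.relevant)
    n = len(rel_idx)
    # map every occupied cell to a relevant cell: itself if relevant, else nearest
    cell_to_label = np.empty(len(grid.counts), dtype=np.int64)
    cell_to_label[rel_idx] = np.arange(n)
    nonrel = np.flatnonzero(~grid.relevant)
    if len(nonrel):
        d = (
            (grid.mean_lab[nonrel][:, None, :] - grid.mean_lab[rel_idx][None, :, :]) ** 2
        ).sum(axis=2)
        cell_to_label[nonrel] = np.argmin(d, axis=1)  # argmin takes the lowest index on ties

    lab_flat = lab.reshape(-1, 3)
    cells = np.floor((lab_flat - _GRID_ORIGIN) / cfg.cell_side).astype(np.int64)
    _, inv = np.unique(cells, axis=0, return_inverse=True)
    labels = cell_to_label[inv].reshape(img.shape[:-1])
    palette = grid.mean_rgb[rel_idx]
    return Quantization(
        palette=palette, labels=labels, n=n, method_tag="colorimetric"
    )
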