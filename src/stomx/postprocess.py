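"""Epidermal-cell counting from a predicted probability mask.

The chain mirrors the post-processing used after semantic segmentation of the
cell network: edge-preserving bilateral smoothing of the probability map,
binarization, a morphological opening of the intracellular class (erosion
then dilation, which seals thin breaks in the cell walls and deletes white
specks), connected-domain labeling, and an area filter that discards domains
smaller than one tenth of the mean domain area (incomplete cells at the image
border).  The survivor count is the epidermal-cell count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage as ndi

from .types import DomainLabeling, ProbMask, WallMask

__all__ = [
    "PostprocessConfig",
    "bilateral_denoise",
    "binarize",
    "opening",
    "label_domains",
    "area_filter",
    "count_cells",
]


@dataclass(frozen=True)
class PostprocessConfig:
    """Tunables of the counting chain.

    ``opening_iterations = 0`` disables the opening step entirely (used when
    counting noiseless ground-truth masks).
    """

    bilateral_radius: int = 4
    bilateral_sigma_range: float = 0.3  # on the [0,1] probability scale
    bilateral_sigma_space: float = 4.0
    binarize_threshold: float = 0.5
    opening_kernel: int = 3
    opening_iterations: int = 1
    area_filter_fraction: float = 0.1
    connectivity: int = 4

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not (0.0 < self.binarize_threshold < 1.0):
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if self.opening_kernel < 1 or self.opening_kernel % 2 == 0:
            raise ValueError("opening_kernel must be an odd integer >= 1")
        if self.opening_iterations < 0:
            raise ValueError("opening_iterations must be >= 0")
        if not (0.0 < self.area_filter_fraction < 1.0):
            raise ValueError("area_filter_fraction must lie in (0, 1)")


def bilateral_denoise(prob: ProbMask, cfg: PostprocessConfig = PostprocessConfig()) -> ProbMask:
    """Edge-preserving bilateral smoothing of the probability map.

    Each output pixel is the normalized sum over the (2r+1)^2 window of
    neighbour values weighted by a spatial Gaussian (sigma_space, in pixels)
    times a range Gaussian (sigma_range, in probability units).  Implemented
    as a vectorized sweep over window offsets; borders use the in-image part
    of the window (weights renormalize).
    """
    x = prob.pixels
    r = cfg.bilateral_radius
    ss2 = 2.0 * cfg.bilateral_sigma_space**2
    sr2 = 2.0 * cfg.bilateral_sigma_range**2
    h, w = x.shape
    num = np.zeros_like(x)
    den = np.zeros_like(x)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            ws = np.exp(-(dx * dx + dy * dy) / ss2)
            ys0, ys1 = max(0, -dy), min(h, h - dy)
            xs0, xs1 = max(0, -dx), min(w, w - dx)
            centre = np.s_[ys0:ys1, xs0:xs1]
            neigh = np.s_[ys0 + dy : ys1 + dy, xs0 + dx : xs1 + dx]
            wgt = ws * np.exp(-((x[neigh] - x[centre]) ** 2) / sr2)
            num[centre] += wgt * x[neigh]
            den[centre] += wgt
    return ProbMask(np.clip(num / den, 0.0, 1.0))


def binarize(smoothed: ProbMask, threshold: float = 0.5) -> WallMask:
    """Threshold the smoothed map: >= threshold -> intracellular (1)."""
    return WallMask((smoothed.pixels >= threshold).astype(np.uint8))


def opening(mask: WallMask, cfg: PostprocessConfig = PostprocessConfig()) -> WallMask:
    """Morphological opening (erosion then dilation) of the intracellular class.

    Erosion of the white class thickens the walls and seals thin breaks;
    the subsequent dilation restores cell area while thin white channels and
    isolated white specks stay removed.  Square structuring element of side
    ``opening_kernel``, repeated ``opening_iterations`` times; 0 iterations
    leave the mask untouched.
    """
    if cfg.opening_iterations == 0:
        return WallMask(mask.pixels.copy())
    st = np.ones((cfg.opening_kernel, cfg.opening_kernel), bool)
    out = ndi.binary_opening(
        mask.pixels.astype(bool), structure=st, iterations=cfg.opening_iterations
    )
    return WallMask(out.astype(np.uint8))


def label_domains(mask: WallMask, connectivity: int = 4) -> DomainLabeling:
    """Label maximal connected intracellular domains and tabulate their areas."""
    if connectivity == 4:
        structure = ndi.generate_binary_structure(2, 1)
    elif connectivity == 8:
        structure = ndi.generate_binary_structure(2, 2)
    else:
        raise ValueError("connectivity must be 4 or 8")
    grid, n = ndi.label(mask.pixels, structure=structure)
    if n == 0:
        return DomainLabeling(grid.astype(np.int32), {})
    areas = ndi.sum_labels(np.ones_like(grid), grid, index=np.arange(1, n + 1))
    return DomainLabeling(
        grid.astype(np.int32), {int(i + 1): int(a) for i, a in enumerate(areas)}
    )


def area_filter(
    labeling: DomainLabeling, fraction: float = 0.1
) -> Tuple[DomainLabeling, int]:
    """Drop domains strictly smaller than ``fraction`` of the mean domain area.

    The mean is computed once over all domains before any removal; surviving
    domains are relabeled contiguously 1..n.  Returns the filtered labeling
    and the survivor count.
    """
    if labeling.n_domains == 0:
        return DomainLabeling(labeling.label_grid.copy(), {}), 0
    areas = labeling.domain_areas
    mean_area = sum(areas.values()) / len(areas)
    threshold = fraction * mean_area
    survivors = [lab for lab, a in sorted(areas.items()) if not (a < threshold)]
    remap = np.zeros(max(areas) + 1, dtype=np.int32)
    for new, lab in enumerate(survivors, start=1):
        remap[lab] = new
    grid = remap[labeling.label_grid]
    new_areas = {remap[lab]: areas[lab] for lab in survivors}
    return DomainLabeling(grid, new_areas), len(survivors)


def count_cells(
    prob: ProbMask, cfg: PostprocessConfig = PostprocessConfig()
) -> int:
    """Full counting chain: bilateral -> binarize -> opening -> label -> filter."""
    smoothed = bilateral_denoise(prob, cfg)
    mask = binarize(smoothed, cfg.binarize_threshold)
    mask = opening(mask, cfg)
    labeling = label_domains(mask, cfg.connectivity)
    _, n_cells = area_filter(labeling, cfg.area_filter_fraction)
    return n_cells
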