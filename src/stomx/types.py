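"""Core value types shared by every stage of the stomatal-index pipeline.

Coordinate convention: all in-memory boxes are 0-based, half-open
``[xmin, xmax) x [ymin, ymax)`` so that ``width = xmax - xmin``.  Pascal VOC
files on disk use 1-based inclusive pixel coordinates; the conversion lives in
:mod:`stomx.annio`.

Mask convention: a :class:`WallMask` stores 0 for the cell-wall / vein /
subsidiary-cell class (annotated black) and 1 for the intracellular class
(annotated white).  Trichomes are annotated white so they do not interfere
with cell segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Magnification",
    "Micrograph",
    "StomaBox",
    "WallMask",
    "ProbMask",
    "DomainLabeling",
    "CountResult",
]


class Magnification(str, Enum):
    X10 = "x10"
    X20 = "x20"
    UNKNOWN = "unknown"


@dataclass
class Micrograph:
    """An RGB leaf-epidermis micrograph (8-bit, H x W x 3)."""

    pixels: np.ndarray
    magnification: Magnification = Magnification.UNKNOWN
    image_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:  # grayscale input: replicate to 3 channels
            px = np.repeat(px[:, :, None], 3, axis=2)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"micrograph pixels must be HxWx3, got {px.shape}")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError(f"micrograph must be at least 64x64, got {px.shape[:2]}")
        self.pixels = px.astype(np.uint8, copy=False)
        self.magnification = Magnification(self.magnification)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def gray(self) -> np.ndarray:
        """Single-channel float view in [0, 255] (channel mean)."""
        return self.pixels.mean(axis=2)


@dataclass(frozen=True, order=True)
class StomaBox:
    """One stoma rectangle, 0-based half-open; ``score`` absent for ground truth."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(
                f"degenerate box ({self.xmin},{self.ymin},{self.xmax},{self.ymax})"
            )
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0,1], got {self.score}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def clip(self, width: int, height: int) -> "StomaBox":
        return StomaBox(
            max(0.0, self.xmin),
            max(0.0, self.ymin),
            min(float(width), self.xmax),
            min(float(height), self.ymax),
            self.score,
        )

    def with_score(self, score: Optional[float]) -> "StomaBox":
        return replace(self, score=score)


@dataclass
class WallMask:
    """Binary wall (0) vs intracellular (1) mask."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"wall mask must be a non-empty 2-D grid, got {px.shape}")
        vals = np.unique(px)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("wall mask values must be 0 (wall) or 1 (intracellular)")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class ProbMask:
    """Per-pixel probability of the intracellular class, in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"probability mask must be non-empty 2-D, got {px.shape}")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("probability mask values must lie in [0, 1]")
        self.pixels = px

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class DomainLabeling:
    """Labeled connected intracellular domains of a binary mask.

    ``label_grid`` holds 0 for the wall class and 1..K for the K domains;
    ``domain_areas`` maps label -> pixel count.
    """

    label_grid: np.ndarray
    domain_areas: dict = field(default_factory=dict)

    @property
    def n_domains(self) -> int:
        return len(self.domain_areas)


@dataclass
class CountResult:
    """Per-image counting outcome: stomata, epidermal cells and stomatal index."""

    image_id: str
    n_stomata: int
    n_cells: int
    stomatal_index_pct: Optional[float]
    stomatal_density_per_mm2: Optional[float] = None
    field_of_view_mm2: Optional[float] = None
    magnification: Magnification = Magnification.UNKNOWN
    failed: bool = False
    error: Optional[str] = None
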