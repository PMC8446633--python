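"""Per-image stomatal index and density from the composed pipeline.

Stomatal index (percent) is ``100 * S / (S + E)`` for S detected stomata and
E counted epidermal cells; it is undefined (reported as missing, not 0) when
both counts are zero.  Stomatal density is stomata per mm^2 of the field of
view — magnification-dependent, unlike the index, which is why the index is
the diagnostically useful trait.
"""

from __future__ import annotations

import time
from typing import Callable, List, Optional, Sequence, Tuple

from .detect import count_stomata
from .metrics import TimingReport, measure_art
from .postprocess import PostprocessConfig, count_cells
from .types import CountResult, Magnification, Micrograph, ProbMask, StomaBox

__all__ = [
    "compute_stomatal_index",
    "compute_density",
    "run_pipeline",
    "DEFAULT_FOV_X10_MM2",
]

# field of view of the reference optics at x10; quartered at x20
DEFAULT_FOV_X10_MM2 = 1.428


def compute_stomatal_index(n_stomata: int, n_cells: int) -> Optional[float]:
    """100 * stomata / (stomata + epidermal cells), or None when undefined."""
    if n_stomata < 0 or n_cells < 0:
        raise ValueError("counts must be non-negative")
    total = n_stomata + n_cells
    if total == 0:
        return None
    return 100.0 * n_stomata / total


def compute_density(n_stomata: int, field_of_view_mm2: float) -> float:
    """Stomata per mm^2 of the imaged field."""
    if field_of_view_mm2 <= 0:
        raise ValueError("field of view must be positive")
    return n_stomata / field_of_view_mm2


def run_pipeline(
    images: Sequence[Micrograph],
    detect_fn: Callable[[Micrograph], Sequence[StomaBox]],
    segment_fn: Callable[[Micrograph], ProbMask],
    post_cfg: PostprocessConfig = PostprocessConfig(),
    fov_mm2: Optional[float] = None,
    score_threshold: float = 0.9,
) -> Tuple[List[CountResult], TimingReport]:
    """Count stomata and epidermal cells on each image and derive the index.

    ``detect_fn`` and ``segment_fn`` are the model inference callables (truth
    oracles can be injected for testing).  Unreadable or failing images are
    recorded as failed rows and the run continues.  Per-stage wall-clock time
    is accumulated into an average-running-time report.
    """
    results: List[CountResult] = []
    t_stoma = t_cell = t_si = 0.0
    for mic in images:
        try:
            t0 = time.perf_counter()
            detections = detect_fn(mic)
            n_stomata = count_stomata(detections, score_threshold)
            t1 = time.perf_counter()
            prob = segment_fn(mic)
            n_cells = count_cells(prob, post_cfg)
            t2 = time.perf_counter()
            si = compute_stomatal_index(n_stomata, n_cells)
            fov = fov_mm2
            if fov is not None and mic.magnification == Magnification.X20:
                fov = fov / 4.0
            density = compute_density(n_stomata, fov) if fov is not None else None
            t3 = time.perf_counter()
            t_stoma += t1 - t0
            t_cell += t2 - t1
            t_si += t3 - t2
            results.append(
                CountResult(
                    image_id=mic.image_id,
                    n_stomata=n_stomata,
                    n_cells=n_cells,
                    stomatal_index_pct=si,
                    stomatal_density_per_mm2=density,
                    field_of_view_mm2=fov,
                    magnification=mic.magnification,
                )
            )
        except Exception as exc:  # noqa: BLE001 - failed rows must not kill the run
            results.append(
                CountResult(
                    image_id=getattr(mic, "image_id", "?"),
                    n_stomata=0,
                    n_cells=0,
                    stomatal_index_pct=None,
                    magnification=getattr(mic, "magnification", Magnification.UNKNOWN),
                    failed=True,
                    error=str(exc),
                )
            )
    n_ok = max(sum(1 for r in results if not r.failed), 1)
    timing = measure_art(t_stoma, t_cell, t_si, n_ok)
    return results, timing
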