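"""Synthetic leaf-epidermis micrographs with exact ground truth.

The generator emulates the abaxial epidermis of a grass leaf: long, thin,
tightly packed pavement cells separated by dark anticlinal walls, a seeded
subset of cells replaced by dumbbell-shaped guard-cell pairs (stomata) with
darker flanking subsidiary tissue, occasional trichomes, and additive
Gaussian illumination noise.  Every scene ships with its exact truth: stoma
bounding boxes, the wall mask in the annotation convention (0 = wall / vein /
subsidiary, 1 = intracellular; trichomes white), and the counts from which
the stomatal index follows.

Tessellation is an anisotropic nearest-seed partition: cell nuclei are drawn
by a seeded jittered-grid point process and pixels are assigned to the
nearest nucleus under a metric that divides x-distances by the elongation
ratio, which produces cells stretched along the leaf axis.  Truth counts are
defined *from the emitted mask itself* (white 4-connected domains), so they
are consistent with any independent flood-fill count by construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Tuple

import numpy as np
from scipy import ndimage as ndi

from .annio import passes_edge_rule, write_image, write_mask, write_voc
from .types import Magnification, Micrograph, StomaBox, WallMask

__all__ = ["SceneSpec", "SceneTruth", "GenerationError", "generate_scene", "generate_dataset"]

# 8-bit rendering tones (walls darker than interiors, stomata darkest)
_TONE_INTERIOR = 185
_TONE_WALL = 60
_TONE_SUBSIDIARY = 110
_TONE_STOMA = 25
_TONE_TRICHOME = 50

# domains smaller than this fraction of the mean cell area are merged into the
# wall class at generation time; strictly above the 1/10 counting threshold so
# truth counts survive the counting chain's area filter unchanged
_CULL_FRACTION = 0.15


class GenerationError(RuntimeError):
    """Raised when a scene specification cannot be satisfied."""


_CROSS = ndi.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Defaults emulate a x10 wheat-like field of view scaled to a 256 px
    canvas: ~40 elongated cells, a stomatal index near the 13-17% range the
    crop exhibits, subsidiary cells present, rare trichomes and mild noise.
    """

    width_px: int = 256
    height_px: int = 256
    cell_elongation: float = 3.0
    target_cell_count: int = 40
    target_stomatal_index_pct: float = 15.0
    subsidiary_cells: bool = True
    trichome_rate: float = 0.3
    noise_sigma: float = 6.0
    wall_thickness_px: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise ValueError("canvas must be at least 64x64")
        if not (0.0 < self.target_stomatal_index_pct < 100.0):
            raise ValueError("target stomatal index must lie in (0, 100)")
        if self.cell_elongation < 1.0:
            raise ValueError("cell_elongation must be >= 1")
        if self.target_cell_count < 1:
            raise ValueError("target_cell_count must be positive")
        if self.trichome_rate < 0 or self.noise_sigma < 0:
            raise ValueError("rates and noise must be non-negative")
        if self.wall_thickness_px < 1:
            raise ValueError("wall_thickness_px must be positive")


@dataclass
class SceneTruth:
    """Exact ground truth of a generated scene."""

    stoma_boxes: List[StomaBox]
    wall_mask: WallMask
    n_stomata: int
    n_epidermal_cells: int
    stomatal_index_pct: float


def _nearest_seed_labels(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Anisotropic nearest-seed partition of the canvas into cells (1..n)."""
    w, h = spec.width_px, spec.height_px
    n = spec.target_cell_count
    # jittered grid of nuclei with the same anisotropy as the target cells:
    # more columns than rows by the elongation factor
    aspect = (w / h) / spec.cell_elongation
    rows = max(1, int(round(np.sqrt(n / max(aspect, 1e-6)))))
    cols = max(1, int(np.ceil(n / rows)))
    cell_w, cell_h = w / cols, h / rows
    if cell_w < 4 * spec.wall_thickness_px or cell_h < 2 * spec.wall_thickness_px:
        raise GenerationError(
            f"cannot fit {n} cells with {spec.wall_thickness_px}px walls on a "
            f"{w}x{h} canvas"
        )
    pts = []
    for r in range(rows):
        for c in range(cols):
            if len(pts) >= n:
                break
            pts.append(
                (
                    (c + 0.5) * cell_w + rng.uniform(-0.3, 0.3) * cell_w,
                    (r + 0.5) * cell_h + rng.uniform(-0.3, 0.3) * cell_h,
                )
            )
    pts = np.asarray(pts)
    ys, xs = np.mgrid[0:h, 0:w]
    # metric: squeeze x so cells elongate along x
    dx = (xs[None] - pts[:, 0, None, None]) / spec.cell_elongation
    dy = ys[None] - pts[:, 1, None, None]
    labels = np.argmin(dx * dx + dy * dy, axis=0).astype(np.int32) + 1
    return labels


def _wall_from_labels(labels: np.ndarray, thickness: int) -> np.ndarray:
    """Boolean wall band of the requested thickness along label boundaries."""
    boundary = np.zeros(labels.shape, bool)
    boundary[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    boundary[:-1, :] |= labels[:-1, :] != labels[1:, :]
    if thickness > 1:
        boundary = ndi.binary_dilation(
            boundary, structure=np.ones((thickness, thickness), bool)
        )
    # canvas border is always wall so edge cells are closed domains
    border = max(1, thickness // 2)
    boundary[:border, :] = True
    boundary[-border:, :] = True
    boundary[:, :border] = True
    boundary[:, -border:] = True
    return boundary


def _dumbbell_footprint(
    shape: Tuple[int, int], cx: float, cy: float, length: float, width: float
) -> np.ndarray:
    """Pixel footprint of a dumbbell-shaped guard-cell pair along the x axis."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    lobe_rx, lobe_ry = 0.22 * length, 0.5 * width
    offs = 0.5 * length - lobe_rx
    lobes = np.zeros(shape, bool)
    for sgn in (-1.0, 1.0):
        lx = cx + sgn * offs
        lobes |= ((xs - lx) / lobe_rx) ** 2 + ((ys - cy) / lobe_ry) ** 2 <= 1.0
    bar = (
        (np.abs(xs - cx) <= offs)
        & (np.abs(ys - cy) <= max(1.0, 0.3 * width))
    )
    return lobes | bar


def generate_scene(spec: SceneSpec) -> Tuple[Micrograph, SceneTruth]:
    """Render one synthetic micrograph and its exact truth record.

    Deterministic: identical specs (including seed) produce bit-identical
    scenes.  The truth never depends on ``noise_sigma`` because layout and
    noise use independent child streams of the seed.
    """
    ss = np.random.SeedSequence(spec.seed)
    layout_rng, noise_rng = [np.random.default_rng(c) for c in ss.spawn(2)]
    w, h = spec.width_px, spec.height_px

    labels = _nearest_seed_labels(spec, layout_rng)
    wall = _wall_from_labels(labels, spec.wall_thickness_px)

    mask = (~wall).astype(np.uint8)  # 1 = intracellular
    gray = np.full((h, w), float(_TONE_INTERIOR))
    gray[wall] = _TONE_WALL

    # --- choose stoma host cells -------------------------------------------
    lab_grid, n_lab = ndi.label(mask, structure=_CROSS)
    areas = ndi.sum_labels(np.ones_like(lab_grid), lab_grid, index=np.arange(1, n_lab + 1))
    n_stomata_target = int(round(spec.target_stomatal_index_pct / 100.0 * n_lab))
    objects = ndi.find_objects(lab_grid)
    eligible = []
    for lab in range(1, n_lab + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        bh, bw = sl[0].stop - sl[0].start, sl[1].stop - sl[1].start
        if bw >= 14 and bh >= 7 and areas[lab - 1] >= 0.5 * areas.mean():
            eligible.append(lab)
    if n_stomata_target > len(eligible):
        raise GenerationError(
            f"spec requests {n_stomata_target} stomata but only {len(eligible)} "
            "cells are large enough to host one"
        )
    hosts = (
        layout_rng.choice(len(eligible), size=n_stomata_target, replace=False)
        if n_stomata_target > 0
        else np.array([], dtype=int)
    )
    hosts = [eligible[int(i)] for i in np.sort(hosts)]

    boxes: List[StomaBox] = []
    for lab in hosts:
        sl = objects[lab - 1]
        cell = lab_grid == lab
        ys, xs = np.nonzero(cell)
        cy, cx = ys.mean(), xs.mean()
        bw = sl[1].stop - sl[1].start
        bh = sl[0].stop - sl[0].start
        length = min(0.62 * bw, 34.0)
        width = min(0.55 * bh, 0.55 * length)
        foot = _dumbbell_footprint((h, w), cx, cy, length, max(4.0, width)) & cell
        if not foot.any():
            continue
        # image: host interior rendered as darker subsidiary tissue, dumbbell darkest
        if spec.subsidiary_cells:
            gray[cell] = _TONE_SUBSIDIARY
        gray[foot] = _TONE_STOMA
        # mask: the guard-cell complex (whole host cell) is not an epidermal cell
        mask[cell] = 0
        fy, fx = np.nonzero(foot)
        boxes.append(
            StomaBox(float(fx.min()), float(fy.min()), float(fx.max() + 1), float(fy.max() + 1))
        )

    # --- trichomes: dark hairs in the image, white (ignored) in the mask ----
    n_tri = int(layout_rng.poisson(spec.trichome_rate))
    for _ in range(n_tri):
        x0 = layout_rng.uniform(0, w)
        y0 = layout_rng.uniform(0, h)
        ang = layout_rng.uniform(0, 2 * np.pi)
        length = layout_rng.uniform(0.15, 0.4) * min(w, h)
        curve = layout_rng.uniform(-0.02, 0.02)
        t = np.arange(0.0, length, 0.5)
        xs_t = x0 + t * np.cos(ang + curve * t)
        ys_t = y0 + t * np.sin(ang + curve * t)
        keep = (xs_t >= 1) & (xs_t < w - 1) & (ys_t >= 1) & (ys_t < h - 1)
        tri = np.zeros((h, w), bool)
        tri[ys_t[keep].astype(int), xs_t[keep].astype(int)] = True
        tri = ndi.binary_dilation(tri, structure=np.ones((2, 2), bool))
        gray[tri] = _TONE_TRICHOME
        mask[tri] = 1

    # --- cull sub-threshold domains so the truth survives area filtering ----
    for _ in range(6):
        lab_grid, n_lab = ndi.label(mask, structure=_CROSS)
        if n_lab == 0:
            break
        areas = ndi.sum_labels(np.ones_like(lab_grid), lab_grid, index=np.arange(1, n_lab + 1))
        small = np.nonzero(areas < _CULL_FRACTION * areas.mean())[0] + 1
        if small.size == 0:
            break
        cull = np.isin(lab_grid, small)
        mask[cull] = 0
        gray[cull] = _TONE_WALL

    lab_grid, n_cells = ndi.label(mask, structure=_CROSS)

    # --- edge visibility rule + final counts --------------------------------
    truth_boxes = [b.clip(w, h) for b in boxes if passes_edge_rule(b, w, h)]
    n_stomata = len(truth_boxes)
    total = n_stomata + n_cells
    si = 100.0 * n_stomata / total if total > 0 else 0.0

    noisy = gray + noise_rng.normal(0.0, spec.noise_sigma, size=gray.shape)
    img8 = np.clip(np.round(noisy), 0, 255).astype(np.uint8)
    mic = Micrograph(
        np.repeat(img8[:, :, None], 3, axis=2),
        Magnification.X10,
        f"scene_{spec.seed}",
    )
    truth = SceneTruth(
        stoma_boxes=truth_boxes,
        wall_mask=WallMask(mask),
        n_stomata=n_stomata,
        n_epidermal_cells=int(n_cells),
        stomatal_index_pct=si,
    )
    return mic, truth


def generate_dataset(n_images: int, spec_template: SceneSpec, out_dir) -> "Path":
    """Write ``n_images`` scenes (PNG + VOC XML + mask PNG) and a CSV manifest.

    Per-image seeds are spawned deterministically from the template seed, so
    rerunning with the same arguments reproduces the dataset byte for byte.
    Returns the manifest path.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "boxes").mkdir(exist_ok=True)
        (out_dir / "masks").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {out_dir}: {exc}") from exc
    manifest = out_dir / "manifest.csv"
    children = np.random.SeedSequence(spec_template.seed).spawn(n_images)
    rows = []
    for i in range(n_images):
        child_seed = int(children[i].generate_state(1, np.uint32)[0] % (2**31))
        spec_i = replace(spec_template, seed=child_seed)
        mic, truth = generate_scene(spec_i)
        image_id = f"img_{i:04d}"
        mic.image_id = image_id
        write_image(mic, out_dir / "images" / f"{image_id}.png")
        write_voc(
            truth.stoma_boxes,
            {"filename": f"{image_id}.png", "width": mic.width, "height": mic.height},
            out_dir / "boxes" / f"{image_id}.xml",
        )
        write_mask(truth.wall_mask, out_dir / "masks" / f"{image_id}.png")
        rows.append(
            {
                "image_id": image_id,
                "seed": child_seed,
                "n_stomata": truth.n_stomata,
                "n_cells": truth.n_epidermal_cells,
                "stomatal_index": f"{truth.stomatal_index_pct:.6f}",
            }
        )
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["image_id", "seed", "n_stomata", "n_cells", "stomatal_index"]
        )
        writer.writeheader()
        writer.writerows(rows)
    return manifest
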