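"""Annotation I/O, dataset splits, and the augmentation / magnification protocols.

Handles Pascal VOC XML box files (1-based inclusive on disk, 0-based half-open
in memory), 0/255 PNG wall masks, deterministic five-fold splits, the offline
rotation augmentation used for detector training (original + 45/90/135 degree
copies), the stochastic online augmentation used for segmenter training
(affine with probability 0.2, 90-degree rotation with probability 0.5), and
the x20-magnification simulation (crop 680x512, cubic x2 upsample).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from lxml import etree
from PIL import Image
from skimage.transform import AffineTransform, resize, warp

from .types import Magnification, Micrograph, StomaBox, WallMask

__all__ = [
    "read_voc",
    "write_voc",
    "read_mask",
    "write_mask",
    "read_image",
    "write_image",
    "make_folds",
    "offline_augment",
    "rotate_with_boxes",
    "online_augment",
    "simulate_20x",
    "visible_length_fraction",
    "passes_edge_rule",
]


# ---------------------------------------------------------------------------
# Pascal VOC boxes
# ---------------------------------------------------------------------------

def read_voc(xml_path) -> List[StomaBox]:
    """Read stoma boxes from a Pascal VOC XML file.

    VOC stores 1-based inclusive pixel coordinates; the returned boxes are
    0-based half-open, so VOC ``(1, 1, 10, 10)`` becomes ``(0, 0, 10, 10)``.
    """
    xml_path = Path(xml_path)
    try:
        tree = etree.parse(str(xml_path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed VOC XML {xml_path}: {exc}") from exc
    boxes: List[StomaBox] = []
    for obj in tree.findall(".//object"):
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ValueError(f"object without bndbox element in {xml_path}")
        vals = {}
        for tag in ("xmin", "ymin", "xmax", "ymax"):
            el = bnd.find(tag)
            if el is None or el.text is None:
                raise ValueError(f"bndbox missing <{tag}> in {xml_path}")
            vals[tag] = float(el.text)
        score_el = obj.find("score")
        score = float(score_el.text) if score_el is not None else None
        # 1-based inclusive -> 0-based half-open: shift mins down by one.
        box = (vals["xmin"] - 1.0, vals["ymin"] - 1.0, vals["xmax"], vals["ymax"])
        if not (box[0] < box[2] and box[1] < box[3]):
            raise ValueError(f"degenerate bndbox {vals} in {xml_path}")
        boxes.append(StomaBox(*box, score=score))
    return boxes


def write_voc(
    boxes: Sequence[StomaBox],
    image_meta: dict,
    xml_path,
) -> None:
    """Write stoma boxes as Pascal VOC XML.

    ``image_meta`` must carry ``filename``, ``width``, ``height`` (``depth``
    optional, default 3).  In-memory half-open coordinates are converted to
    1-based inclusive integers.
    """
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = str(image_meta.get("filename", ""))
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(int(image_meta["width"]))
    etree.SubElement(size, "height").text = str(int(image_meta["height"]))
    etree.SubElement(size, "depth").text = str(int(image_meta.get("depth", 3)))
    for box in boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = "stoma"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(int(round(box.xmin)) + 1)
        etree.SubElement(bnd, "ymin").text = str(int(round(box.ymin)) + 1)
        etree.SubElement(bnd, "xmax").text = str(int(round(box.xmax)))
        etree.SubElement(bnd, "ymax").text = str(int(round(box.ymax)))
        if box.score is not None:
            etree.SubElement(obj, "score").text = repr(box.score)
    Path(xml_path).write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="utf-8")
    )


# ---------------------------------------------------------------------------
# PNG masks and images
# ---------------------------------------------------------------------------

def read_mask(png_path) -> WallMask:
    """Read a 0/255 annotation PNG: values <= 127 -> wall (0), > 127 -> 1."""
    arr = np.asarray(Image.open(png_path).convert("L"))
    if arr.size == 0:
        raise ValueError(f"empty mask image {png_path}")
    return WallMask((arr > 127).astype(np.uint8))


def write_mask(mask: WallMask, png_path) -> None:
    """Write a wall mask as a 0/255 grayscale PNG."""
    Image.fromarray((mask.pixels * 255).astype(np.uint8)).save(png_path)


def read_image(path, magnification=Magnification.UNKNOWN, image_id: str = "") -> Micrograph:
    arr = np.asarray(Image.open(path).convert("RGB"))
    return Micrograph(arr, magnification, image_id or Path(path).stem)


def write_image(mic: Micrograph, path) -> None:
    Image.fromarray(mic.pixels).save(path)


# ---------------------------------------------------------------------------
# Cross-validation folds
# ---------------------------------------------------------------------------

def make_folds(image_ids: Sequence[str], k: int = 5, seed: int = 0) -> Dict[str, int]:
    """Partition image ids into k mutually exclusive folds (1..k).

    Deterministic in ``seed``; fold sizes differ by at most one.
    """
    ids = list(image_ids)
    if len(ids) < k:
        raise ValueError(f"need at least k={k} ids, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError("image ids must be unique")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return {ids[int(j)]: (pos % k) + 1 for pos, j in enumerate(order)}


# ---------------------------------------------------------------------------
# Offline augmentation: rotations of 45, 90 and 135 degrees
# ---------------------------------------------------------------------------

def _rotation_transform(angle_deg: float, h: int, w: int):
    """Forward rotation about the image centre with canvas expansion.

    Works in edge coordinates (the image occupies [0,w]x[0,h]); returns
    ``(fwd, rot, centre, offset, out_h, out_w)`` where ``fwd`` maps input
    (x, y) points to output points.
    """
    theta = math.radians(angle_deg)
    cx, cy = w / 2.0, h / 2.0
    corners = np.array([[0, 0], [w, 0], [0, h], [w, h]], float)
    rot = np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )
    rc = (corners - [cx, cy]) @ rot.T
    minx, miny = rc.min(axis=0)
    maxx, maxy = rc.max(axis=0)
    out_w = int(round(maxx - minx))
    out_h = int(round(maxy - miny))

    def fwd(pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float)
        return (pts - [cx, cy]) @ rot.T - [minx, miny]

    return fwd, rot, (cx, cy), (minx, miny), out_h, out_w


def rotate_with_boxes(
    mic: Micrograph,
    boxes: Sequence[StomaBox],
    angle_deg: float,
    fill: int = 255,
    mask: Optional[WallMask] = None,
):
    """Rotate an image (and optional mask) with its boxes, expanding the canvas.

    90-degree multiples are exact grid bijections (no interpolation).  For
    other angles the image is rotated with bilinear interpolation on an
    expanded canvas filled with ``fill`` (background white), masks with
    nearest-neighbour and wall-class fill, and each box is replaced by the
    axis-aligned circumscribed rectangle of its four rotated corners.
    """
    h, w = mic.height, mic.width
    angle = angle_deg % 360.0
    if angle % 90.0 == 0.0:
        k = int(angle // 90) % 4
        px = np.rot90(mic.pixels, k=k, axes=(1, 0))  # clockwise in (x,y) terms
        # np.rot90 with axes=(1,0) rotates the grid so that the forward map of
        # pixel (x, y) matches the analytic rotation below.
        out = np.ascontiguousarray(px)
        new_mask = (
            WallMask(np.ascontiguousarray(np.rot90(mask.pixels, k=k, axes=(1, 0))))
            if mask is not None
            else None
        )
        fwd, *_ = _rotation_transform(angle, h, w)
    else:
        fwd, rot, (cx, cy), (minx, miny), out_h, out_w = _rotation_transform(angle, h, w)
        # inverse map in pixel-centre coords: src = (out + 0.5 + [minx,miny]) @ rot
        # + centre - 0.5, expressed as an affine matrix for warp()
        t = (np.array([0.5 + minx, 0.5 + miny]) @ rot) + [cx, cy] - 0.5
        matrix = np.eye(3)
        matrix[:2, :2] = rot.T
        matrix[:2, 2] = t
        inverse = AffineTransform(matrix=matrix)

        out = np.stack(
            [
                warp(
                    mic.pixels[:, :, c].astype(float),
                    inverse_map=inverse,
                    output_shape=(out_h, out_w),
                    order=1,
                    cval=float(fill),
                    preserve_range=True,
                )
                for c in range(3)
            ],
            axis=2,
        )
        out = np.clip(np.round(out), 0, 255).astype(np.uint8)
        new_mask = None
        if mask is not None:
            m = warp(
                mask.pixels.astype(float),
                inverse_map=inverse,
                output_shape=(out_h, out_w),
                order=0,
                cval=0.0,
                preserve_range=True,
            )
            new_mask = WallMask((m > 0.5).astype(np.uint8))
    out_h2, out_w2 = out.shape[:2]
    new_boxes = []
    for b in boxes:
        corners = np.array(
            [
                [b.xmin, b.ymin],
                [b.xmax, b.ymin],
                [b.xmin, b.ymax],
                [b.xmax, b.ymax],
            ]
        )
        rc = fwd(corners)
        nb = StomaBox(
            float(rc[:, 0].min()),
            float(rc[:, 1].min()),
            float(rc[:, 0].max()),
            float(rc[:, 1].max()),
            b.score,
        ).clip(out_w2, out_h2)
        new_boxes.append(nb)
    new_mic = Micrograph(out, mic.magnification, f"{mic.image_id}_rot{int(angle_deg)}")
    if mask is not None:
        return new_mic, new_boxes, new_mask
    return new_mic, new_boxes


def offline_augment(samples: Iterable[tuple]) -> List[tuple]:
    """Expand an annotated detection set by rotations of 45, 90 and 135 degrees.

    ``samples`` is an iterable of ``(Micrograph, [StomaBox, ...])`` pairs; the
    result keeps each original followed by its three rotated copies, so the
    image count multiplies by four.
    """
    out: List[tuple] = []
    for mic, boxes in samples:
        out.append((mic, list(boxes)))
        for angle in (45.0, 90.0, 135.0):
            out.append(rotate_with_boxes(mic, boxes, angle))
    return out


# ---------------------------------------------------------------------------
# Online augmentation for segmentation training
# ---------------------------------------------------------------------------

def online_augment(
    image: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    p_affine: float = 0.2,
    p_rot90: float = 0.5,
    max_rotation_deg: float = 10.0,
    max_shear_deg: float = 10.0,
    max_scale: float = 0.05,
    max_translate: float = 0.05,
) -> Tuple[np.ndarray, np.ndarray]:
    """Jointly augment an image/mask pair for one training draw.

    A small random affine perturbation is applied with probability
    ``p_affine`` and a 90-degree rotation with probability ``p_rot90``; both
    transforms are applied identically to image and mask (bilinear vs
    nearest interpolation).  The draw order is fixed (affine coin first) so a
    seeded ``rng`` reproduces the augmentation exactly.
    """
    img = np.asarray(image)
    msk = np.asarray(mask)
    if img.shape[:2] != msk.shape[:2]:
        raise ValueError("image and mask must share height/width")
    if rng.random() < p_affine:
        h, w = msk.shape[:2]
        rot = math.radians(rng.uniform(-max_rotation_deg, max_rotation_deg))
        shear = math.radians(rng.uniform(-max_shear_deg, max_shear_deg))
        scale = 1.0 + rng.uniform(-max_scale, max_scale)
        tx = rng.uniform(-max_translate, max_translate) * w
        ty = rng.uniform(-max_translate, max_translate) * h
        centre = AffineTransform(translation=(-w / 2, -h / 2))
        tf = (
            centre
            + AffineTransform(rotation=rot, shear=shear, scale=(scale, scale))
            + AffineTransform(translation=(w / 2 + tx, h / 2 + ty))
        )
        img = warp(
            img.astype(float), tf.inverse, order=1, mode="edge", preserve_range=True
        )
        msk = warp(
            msk.astype(float), tf.inverse, order=0, mode="edge", preserve_range=True
        )
        if image.dtype == np.uint8:
            img = np.clip(np.round(img), 0, 255)
        msk = (msk > 0.5).astype(mask.dtype)
        img = img.astype(image.dtype)
    if rng.random() < p_rot90:
        img = np.ascontiguousarray(np.rot90(img))
        msk = np.ascontiguousarray(np.rot90(msk))
    return img, msk


# ---------------------------------------------------------------------------
# x20 magnification simulation
# ---------------------------------------------------------------------------

def visible_length_fraction(box: StomaBox, xmin, ymin, xmax, ymax) -> float:
    """Fraction of the box's major-axis length inside the window.

    Returns 0 when there is no overlap along the minor axis.
    """
    ox = max(0.0, min(box.xmax, xmax) - max(box.xmin, xmin))
    oy = max(0.0, min(box.ymax, ymax) - max(box.ymin, ymin))
    if ox <= 0 or oy <= 0:
        return 0.0
    if box.width >= box.height:
        return ox / box.width
    return oy / box.height


def passes_edge_rule(box: StomaBox, width: int, height: int) -> bool:
    """Annotation visibility rule: keep a stoma only if more than half of its
    length lies inside the image."""
    return visible_length_fraction(box, 0, 0, width, height) > 0.5


def simulate_20x(
    mic: Micrograph,
    boxes: Sequence[StomaBox] = (),
    mask: Optional[WallMask] = None,
    crop_size: Tuple[int, int] = (680, 512),
    corner: Optional[Tuple[int, int]] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Simulate a x20 acquisition from a x10 micrograph.

    Crops a ``crop_size`` (width, height) window — top-left by default, a
    seeded random corner when ``rng`` is given, or an explicit ``corner``
    (x, y) — then upscales x2 with cubic interpolation.  Boxes are shifted,
    filtered by the half-at-edge visibility rule, clipped and doubled; the
    mask (if given) is cropped and upscaled with nearest-neighbour.
    """
    cw, ch = crop_size
    if mic.width < cw or mic.height < ch:
        raise ValueError(
            f"image {mic.width}x{mic.height} smaller than crop window {cw}x{ch}"
        )
    if corner is None:
        if rng is not None:
            corner = (
                int(rng.integers(0, mic.width - cw + 1)),
                int(rng.integers(0, mic.height - ch + 1)),
            )
        else:
            corner = (0, 0)
    x0, y0 = corner
    if not (0 <= x0 <= mic.width - cw and 0 <= y0 <= mic.height - ch):
        raise ValueError(f"crop corner {corner} out of range")
    crop = mic.pixels[y0 : y0 + ch, x0 : x0 + cw]
    up = resize(
        crop.astype(float),
        (2 * ch, 2 * cw, 3),
        order=3,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    up = np.clip(np.round(up), 0, 255).astype(np.uint8)
    out_mic = Micrograph(up, Magnification.X20, f"{mic.image_id}_20x")

    out_boxes: List[StomaBox] = []
    for b in boxes:
        shifted = StomaBox(b.xmin - x0, b.ymin - y0, b.xmax - x0, b.ymax - y0, b.score)
        if visible_length_fraction(shifted, 0, 0, cw, ch) <= 0.5:
            continue
        clipped = shifted.clip(cw, ch)
        out_boxes.append(
            StomaBox(
                2 * clipped.xmin, 2 * clipped.ymin, 2 * clipped.xmax, 2 * clipped.ymax,
                b.score,
            )
        )
    if mask is not None:
        mcrop = mask.pixels[y0 : y0 + ch, x0 : x0 + cw]
        mup = resize(
            mcrop.astype(float), (2 * ch, 2 * cw), order=0, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
        out_mask = WallMask((mup > 0.5).astype(np.uint8))
        return out_mic, out_boxes, out_mask
    return out_mic, out_boxes
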