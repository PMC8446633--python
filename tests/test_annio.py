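"""Annotation I/O, folds, augmentation and magnification protocols."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from PIL import Image
from skimage.transform import resize as sk_resize

from stomx import (
    Magnification,
    Micrograph,
    SceneSpec,
    StomaBox,
    WallMask,
    generate_scene,
    make_folds,
    offline_augment,
    online_augment,
    read_mask,
    read_voc,
    rotate_with_boxes,
    simulate_20x,
    write_mask,
    write_voc,
)

from conftest import flood_fill_count


# ---------------------------------------------------------------------------
# Pascal VOC
# ---------------------------------------------------------------------------

def test_voc_round_trip_preserves_boxes(tmp_path):
    boxes = [StomaBox(0, 0, 10, 10), StomaBox(5, 7, 30, 22), StomaBox(100, 3, 140, 19)]
    path = tmp_path / "a.xml"
    write_voc(boxes, {"filename": "a.png", "width": 200, "height": 100}, path)
    back = read_voc(path)
    assert [(b.xmin, b.ymin, b.xmax, b.ymax) for b in back] == [
        (b.xmin, b.ymin, b.xmax, b.ymax) for b in boxes
    ]


def test_voc_one_based_inclusive_maps_to_half_open(tmp_path):
    path = tmp_path / "conv.xml"
    path.write_text(
        "<annotation><object><name>stoma</name><bndbox>"
        "<xmin>1</xmin><ymin>1</ymin><xmax>10</xmax><ymax>10</ymax>"
        "</bndbox></object></annotation>"
    )
    (box,) = read_voc(path)
    assert (box.xmin, box.ymin, box.xmax, box.ymax) == (0, 0, 10, 10)


def test_voc_empty_object_list_round_trips(tmp_path):
    path = tmp_path / "empty.xml"
    write_voc([], {"filename": "e.png", "width": 64, "height": 64}, path)
    assert read_voc(path) == []


def test_voc_malformed_and_degenerate_inputs_raise(tmp_path):
    bad = tmp_path / "bad.xml"
    bad.write_text("<annotation><object>")
    with pytest.raises(ValueError, match="malformed"):
        read_voc(bad)
    degen = tmp_path / "degen.xml"
    degen.write_text(
        "<annotation><object><bndbox>"
        "<xmin>10</xmin><ymin>1</ymin><xmax>5</xmax><ymax>10</ymax>"
        "</bndbox></object></annotation>"
    )
    with pytest.raises(ValueError):
        read_voc(degen)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def test_mask_round_trip_and_threshold_rule(tmp_path):
    rng = np.random.default_rng(0)
    mask = WallMask(rng.integers(0, 2, (40, 60)).astype(np.uint8))
    path = tmp_path / "m.png"
    write_mask(mask, path)
    assert np.array_equal(read_mask(path).pixels, mask.pixels)

    gray = np.full((10, 10), 30, np.uint8)
    gray[:5] = 200
    Image.fromarray(gray).save(tmp_path / "g.png")
    back = read_mask(tmp_path / "g.png")
    assert back.pixels[:5].all() and not back.pixels[5:].any()

    allwhite = tmp_path / "w.png"
    Image.fromarray(np.full((8, 8), 255, np.uint8)).save(allwhite)
    assert read_mask(allwhite).pixels.all()


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def test_five_folds_of_one_thousand_are_mutually_exclusive_and_200_each():
    ids = [f"img_{i}" for i in range(1000)]
    folds = make_folds(ids, k=5, seed=1)
    assert set(folds) == set(ids)
    sizes = {f: sum(1 for v in folds.values() if v == f) for f in range(1, 6)}
    assert sizes == {1: 200, 2: 200, 3: 200, 4: 200, 5: 200}


def test_fold_determinism_and_small_n():
    ids = [f"i{k}" for k in range(10)]
    f1 = make_folds(ids, k=5, seed=3)
    f2 = make_folds(ids, k=5, seed=3)
    assert f1 == f2
    sizes = [sum(1 for v in f1.values() if v == f) for f in range(1, 6)]
    assert sizes == [2, 2, 2, 2, 2]
    with pytest.raises(ValueError):
        make_folds(["a", "b"], k=5, seed=0)


# ---------------------------------------------------------------------------
# offline augmentation
# ---------------------------------------------------------------------------

def test_offline_augmentation_quadruples_and_empty_stays_empty():
    mics = [
        (Micrograph(np.full((64, 64, 3), 200, np.uint8), image_id=f"m{i}"),
         [StomaBox(10, 10, 30, 20)])
        for i in range(6)
    ]
    out = offline_augment(mics)
    assert len(out) == 24
    assert offline_augment([]) == []


def test_90_degree_rotation_permutes_box_coordinates_exactly():
    w = h = 64
    mic = Micrograph(np.zeros((h, w, 3), np.uint8))
    box = StomaBox(10, 20, 30, 26)
    _, (rot,) = rotate_with_boxes(mic, [box], 90.0)
    # (x, y) -> (h - y, x) in edge coordinates
    assert (rot.xmin, rot.ymin, rot.xmax, rot.ymax) == (
        h - box.ymax, box.xmin, h - box.ymin, box.xmax,
    )


def test_45_degree_rotation_expands_canvas_and_circumscribes_boxes():
    px = np.full((64, 64, 3), 80, np.uint8)
    mic = Micrograph(px)
    box = StomaBox(24, 28, 40, 36)
    rot_mic, (rot_box,) = rotate_with_boxes(mic, [box], 45.0)
    assert rot_mic.height > 64 and rot_mic.width > 64
    # corners fill with background white
    assert rot_mic.pixels[0, 0, 0] == 255
    # circumscribed rectangle of a wxh box rotated 45° has side (w+h)/sqrt(2)
    side = (box.width + box.height) / np.sqrt(2)
    assert rot_box.width == pytest.approx(side, abs=1e-6)
    assert rot_box.height == pytest.approx(side, abs=1e-6)


def test_rotation_by_90_multiples_preserves_mask_domain_count():
    _, truth = generate_scene(SceneSpec(seed=4))
    mic = Micrograph(np.zeros((256, 256, 3), np.uint8))
    n0, areas0 = flood_fill_count(truth.wall_mask.pixels)
    for angle in (90.0, 180.0, 270.0):
        _, _, rot_mask = rotate_with_boxes(mic, [], angle, mask=truth.wall_mask)
        n, areas = flood_fill_count(rot_mask.pixels)
        assert (n, areas) == (n0, areas0)


# ---------------------------------------------------------------------------
# online augmentation
# ---------------------------------------------------------------------------

def test_online_augment_identity_when_both_draws_miss():
    img = np.arange(256, dtype=np.uint8).reshape(16, 16)
    mask = (img > 128).astype(np.uint8)
    out_i, out_m = online_augment(img, mask, np.random.default_rng(0),
                                  p_affine=0.0, p_rot90=0.0)
    assert np.array_equal(out_i, img) and np.array_equal(out_m, mask)


def test_online_augment_rot90_applies_identically_to_image_and_mask():
    rng = np.random.default_rng(1)
    img = np.zeros((16, 16), np.float64)
    img[2, 3] = 1.0  # marker
    mask = np.zeros((16, 16), np.uint8)
    mask[2, 3] = 1
    for _ in range(20):
        out_i, out_m = online_augment(img, mask, rng, p_affine=0.0, p_rot90=1.0)
        assert np.array_equal(out_i, np.rot90(img))
        assert np.array_equal(out_m, np.rot90(mask))


def test_online_augment_transform_frequencies_match_probabilities():
    rng = np.random.default_rng(12345)
    img = np.linspace(0, 1, 256).reshape(16, 16)
    mask = (img > 0.5).astype(np.uint8)
    n = 2000
    n_rot = sum(
        not np.array_equal(online_augment(img, mask, rng, p_affine=0.0)[0], img)
        for _ in range(n)
    )
    n_aff = sum(
        not np.array_equal(
            online_augment(img, mask, rng, p_rot90=0.0)[0], img
        )
        for _ in range(n)
    )
    # 4-sigma binomial bands around 0.5 and 0.2
    assert abs(n_rot / n - 0.5) < 4 * np.sqrt(0.25 / n)
    assert abs(n_aff / n - 0.2) < 4 * np.sqrt(0.16 / n)


def test_online_augment_is_reproducible_for_a_fixed_seed():
    img = np.linspace(0, 255, 256).reshape(16, 16)
    mask = (img > 100).astype(np.uint8)
    a = online_augment(img, mask, np.random.default_rng(9))
    b = online_augment(img, mask, np.random.default_rng(9))
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


# ---------------------------------------------------------------------------
# x20 simulation
# ---------------------------------------------------------------------------

def test_simulate_20x_full_protocol_dimensions_and_cubic_resize():
    rng = np.random.default_rng(0)
    px = rng.integers(0, 256, (1024, 1360, 3)).astype(np.uint8)
    mic = Micrograph(px, Magnification.X10, "full")
    out, _ = simulate_20x(mic, [])
    assert (out.height, out.width) == (1024, 1360)
    assert out.magnification == Magnification.X20
    expected = sk_resize(px[:512, :680].astype(float), (1024, 1360, 3), order=3,
                         mode="edge", anti_aliasing=False, preserve_range=True)
    expected = np.clip(np.round(expected), 0, 255).astype(np.uint8)
    assert np.array_equal(out.pixels, expected)


def test_simulate_20x_box_bookkeeping():
    px = np.full((1024, 1360, 3), 128, np.uint8)
    mic = Micrograph(px, Magnification.X10)
    inside = StomaBox(100, 100, 140, 120)
    outside = StomaBox(700, 600, 740, 620)   # beyond the 680x512 window
    straddle = StomaBox(660, 100, 700, 120)  # half in: 20/40 = 0.5, not > 0.5
    out, boxes = simulate_20x(mic, [inside, outside, straddle])
    assert len(boxes) == 1
    b = boxes[0]
    assert (b.xmin, b.ymin, b.xmax, b.ymax) == (200, 200, 280, 240)


def test_simulate_20x_rejects_small_images():
    mic = Micrograph(np.zeros((256, 256, 3), np.uint8))
    with pytest.raises(ValueError, match="smaller than crop"):
        simulate_20x(mic, [])


@given(st.integers(0, 2**31 - 1))
def test_simulate_20x_random_corner_is_seed_reproducible(seed):
    px = (np.indices((128, 160)).sum(axis=0) % 256).astype(np.uint8)
    mic = Micrograph(np.repeat(px[:, :, None], 3, axis=2))
    a, _ = simulate_20x(mic, [], crop_size=(96, 64), rng=np.random.default_rng(seed))
    b, _ = simulate_20x(mic, [], crop_size=(96, 64), rng=np.random.default_rng(seed))
    assert np.array_equal(a.pixels, b.pixels)
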