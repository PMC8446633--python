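"""Training contracts: learning curves, determinism, checkpoints, transfer.

The expensive session fixtures (detector and segmenter trained on 40
synthetic scenes) live in conftest; short auxiliary trainings here use small
subsets so the whole module stays within a few minutes.
"""

import numpy as np
import pytest

from stomx import (
    DetectorConfig,
    Micrograph,
    SceneSpec,
    SegConfig,
    count_stomata,
    detect,
    dice,
    finetune_detector,
    finetune_segmenter,
    generate_pseudo_labels,
    generate_scene,
    iou,
    load_detector,
    load_segmenter,
    predict_mask,
    read_mask,
    save_detector,
    save_segmenter,
    train_detector,
    train_segmenter,
)
from stomx.detect import DetectorModel, _DetNet
from stomx.annio import rotate_with_boxes


# ---------------------------------------------------------------------------
# segmenter
# ---------------------------------------------------------------------------

def test_segmenter_loss_decreases_and_reaches_heldout_dice(
    trained_segmenter, heldout_scenes
):
    losses = [e["loss"] for e in trained_segmenter.log]
    assert losses[0] > min(losses)
    dices = [
        dice(predict_mask(trained_segmenter, mic).pixels >= 0.5,
             truth.wall_mask.pixels > 0.5)
        for mic, truth in heldout_scenes
    ]
    assert np.mean(dices) >= 0.8


def test_segmenter_prediction_is_bounded_sized_and_deterministic(
    trained_segmenter, heldout_scenes
):
    mic, _ = heldout_scenes[0]
    a = predict_mask(trained_segmenter, mic)
    b = predict_mask(trained_segmenter, mic)
    assert a.shape == (mic.height, mic.width)
    assert 0.0 <= a.pixels.min() and a.pixels.max() <= 1.0
    assert np.array_equal(a.pixels, b.pixels)


def test_segmenter_training_is_seed_deterministic(train_scenes):
    pairs = [(m, t.wall_mask) for m, t in train_scenes[:4]]
    cfg = SegConfig.small(seed=3, epochs=2, input_size=(64, 64), base_width=4)
    l1 = train_segmenter(pairs, cfg).log[-1]["loss"]
    l2 = train_segmenter(pairs, cfg).log[-1]["loss"]
    assert l1 == l2


def test_segmenter_rejects_empty_training_set():
    with pytest.raises(ValueError):
        train_segmenter([], SegConfig.small())


def test_segmenter_checkpoint_round_trip(trained_segmenter, heldout_scenes, tmp_path):
    path = tmp_path / "seg.npz"
    save_segmenter(trained_segmenter, path)
    back = load_segmenter(path)
    mic, _ = heldout_scenes[1]
    assert np.array_equal(
        predict_mask(back, mic).pixels, predict_mask(trained_segmenter, mic).pixels
    )


def test_pseudo_labels_written_in_mask_convention(trained_segmenter, heldout_scenes, tmp_path):
    images = [mic for mic, _ in heldout_scenes[:3]]
    paths = generate_pseudo_labels(trained_segmenter, images, tmp_path / "pl")
    assert len(paths) == 3
    for path, (mic, truth) in zip(paths, heldout_scenes[:3]):
        mask = read_mask(path)  # validates the 0/255 convention
        assert mask.shape == (mic.height, mic.width)


def test_finetune_segmenter_lr_zero_is_a_no_op(trained_segmenter, heldout_scenes):
    mic, _ = heldout_scenes[2]
    before = predict_mask(trained_segmenter, mic).pixels.copy()
    pairs = [(m, t.wall_mask) for m, t in heldout_scenes[:2]]
    ft = finetune_segmenter(trained_segmenter, pairs, lr=0.0, epochs=1, augment=False)
    assert np.array_equal(predict_mask(ft, mic).pixels, before)


def test_finetune_segmenter_adapts_to_an_inverted_staining_family(trained_segmenter):
    fam = [generate_scene(SceneSpec(seed=100 + s, cell_elongation=1.5)) for s in range(16)]
    inverted = [
        (Micrograph(255 - m.pixels, m.magnification, m.image_id), t) for m, t in fam
    ]
    test_pairs = inverted[10:]

    def mean_dice(model):
        return np.mean(
            [dice(predict_mask(model, m).pixels >= 0.5, t.wall_mask.pixels > 0.5)
             for m, t in test_pairs]
        )

    before = mean_dice(trained_segmenter)
    ft = finetune_segmenter(
        trained_segmenter,
        [(m, t.wall_mask) for m, t in inverted[:10]],
        lr=0.05, epochs=8, seed=1,
    )
    after = mean_dice(ft)
    assert after > before + 0.3


# ---------------------------------------------------------------------------
# detector
# ---------------------------------------------------------------------------

def test_detector_loss_decreases_over_first_epochs(trained_detector):
    losses = [e["loss"] for e in trained_detector.log]
    assert losses[0] > losses[1] > losses[2]
    assert losses[-1] < losses[0]


def test_detector_counts_heldout_stomata_accurately(trained_detector, heldout_scenes):
    accs = []
    for mic, truth in heldout_scenes:
        n = count_stomata(detect(trained_detector, mic))
        accs.append(1.0 - abs(n - truth.n_stomata) / truth.n_stomata)
    assert np.mean(accs) >= 0.9


def test_detector_localizes_heldout_truth_boxes(trained_detector, heldout_scenes):
    """Nearly every held-out stoma is matched by a detection at IoU > 0.6,
    and most images are matched completely."""
    total = matched = 0
    fully_matched_images = 0
    for mic, truth in heldout_scenes:
        dets = detect(trained_detector, mic)
        hits = [any(iou(d, tb) > 0.6 for d in dets) for tb in truth.stoma_boxes]
        total += len(hits)
        matched += sum(hits)
        fully_matched_images += all(hits)
    assert matched / total >= 0.95
    assert fully_matched_images >= 0.7 * len(heldout_scenes)


def test_detector_training_is_seed_deterministic(train_scenes):
    samples = [(m, t.stoma_boxes) for m, t in train_scenes[:4]]
    cfg = DetectorConfig.small(seed=3, epochs=2)
    l1 = train_detector(samples, cfg).log[-1]["loss"]
    l2 = train_detector(samples, cfg).log[-1]["loss"]
    assert l1 == l2


def test_detector_rejects_empty_set_and_zero_epochs(train_scenes):
    with pytest.raises(ValueError):
        train_detector([], DetectorConfig.small())
    with pytest.raises(ValueError):
        DetectorConfig.small(epochs=0)


def test_untrained_head_on_blank_image_counts_zero():
    cfg = DetectorConfig.small(seed=0)
    model = DetectorModel(_DetNet(cfg, np.random.default_rng(0)), cfg)
    blank = Micrograph(np.full((256, 256, 3), 255, np.uint8))
    assert count_stomata(detect(model, blank)) == 0


def test_detector_checkpoint_round_trip(trained_detector, heldout_scenes, tmp_path):
    path = tmp_path / "det.npz"
    save_detector(trained_detector, path)
    back = load_detector(path)
    mic, _ = heldout_scenes[0]
    assert detect(back, mic) == detect(trained_detector, mic)


def test_finetune_detector_lr_zero_keeps_parameters(trained_detector):
    before = [p.copy() for p, _ in trained_detector.net.params()]
    ft = finetune_detector(trained_detector, [], lr=0.0)
    for (p, _), old in zip(ft.net.params(), before):
        assert np.array_equal(p, old)


def test_finetune_detector_on_source_does_not_degrade(
    trained_detector, train_scenes, tmp_path
):
    # run on a copy so the session fixture stays pristine
    path = tmp_path / "det.npz"
    save_detector(trained_detector, path)
    model = load_detector(path)
    base_loss = model.log[-1]["loss"]
    samples = [(m, t.stoma_boxes) for m, t in train_scenes[:10]]
    ft = finetune_detector(model, samples, lr=0.0001, epochs=3, seed=2)
    assert ft.log[-1]["loss"] <= 1.10 * base_loss


def test_finetune_detector_transfers_to_a_rotated_family(
    trained_detector, tmp_path
):
    fam = [generate_scene(SceneSpec(seed=100 + s)) for s in range(16)]
    rotated = [rotate_with_boxes(m, t.stoma_boxes, 90.0) for m, t in fam]
    truth_n = [t.n_stomata for _, t in fam]

    def mean_acc(model, idx):
        return np.mean(
            [1.0 - abs(count_stomata(detect(model, rotated[i][0])) - truth_n[i]) / truth_n[i]
             for i in idx]
        )

    heldout = range(10, 16)
    before = mean_acc(trained_detector, heldout)
    path = tmp_path / "det.npz"
    save_detector(trained_detector, path)
    ft = finetune_detector(
        load_detector(path), rotated[:10], lr=0.02, epochs=30, seed=1
    )
    after = mean_acc(ft, heldout)
    assert after > before + 0.3
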