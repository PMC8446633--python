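"""Train the desk-scale detector and segmenter, then measure stomatal index.

This is the whole method end to end on synthetic data: an anchor-based
detector counts stomata (score > 0.9), a U-Net-style segmenter predicts the
cell network, morphological post-processing counts epidermal cells, and the
stomatal index follows from the two counts.  Takes a few minutes on one CPU;
shrink N_TRAIN or the epochs for a faster (less accurate) demonstration.
"""

import numpy as np

from stomx import (
    DetectorConfig,
    PostprocessConfig,
    SceneSpec,
    SegConfig,
    counting_accuracy,
    detect,
    generate_scene,
    index_accuracy,
    predict_mask,
    train_detector,
    train_segmenter,
)
from stomx.pipeline import run_pipeline

N_TRAIN, N_TEST = 40, 10
scenes = [generate_scene(SceneSpec(seed=s)) for s in range(N_TRAIN + N_TEST)]
train, test = scenes[:N_TRAIN], scenes[N_TRAIN:]

detector = train_detector([(m, t.stoma_boxes) for m, t in train], DetectorConfig.small(seed=0))
segmenter = train_segmenter([(m, t.wall_mask) for m, t in train], SegConfig.small(seed=0))

results, timing = run_pipeline(
    [m for m, _ in test],
    lambda m: detect(detector, m),
    lambda m: predict_mask(segmenter, m),
    PostprocessConfig(),
)

s_accs, i_accs = [], []
for res, (_, truth) in zip(results, test):
    s_accs.append(counting_accuracy(res.n_stomata, truth.n_stomata))
    i_accs.append(index_accuracy(res.stomatal_index_pct, truth.stomatal_index_pct))
    print(
        f"{res.image_id}: stomata {res.n_stomata} (truth {truth.n_stomata}), "
        f"cells {res.n_cells} (truth {truth.n_epidermal_cells}), "
        f"index {res.stomatal_index_pct:.2f}% (truth {truth.stomatal_index_pct:.2f}%)"
    )
print(f"mean stomata counting accuracy: {np.mean(s_accs):.3f}")
print(f"mean stomatal-index accuracy:  {np.mean(i_accs):.3f}")
print(f"average running time: {timing.art:.2f} s/image")
# Counting accuracy is 1 - |auto - manual| / manual; index accuracy applies
# the same form to the index values, so 1.0 means a perfect measurement.
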