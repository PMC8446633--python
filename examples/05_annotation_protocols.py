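"""Annotation I/O and the dataset protocols: VOC boxes, folds, augmentation,
x20 simulation.
"""

import tempfile
from pathlib import Path

import numpy as np

from stomx import (
    Micrograph,
    SceneSpec,
    StomaBox,
    generate_dataset,
    make_folds,
    offline_augment,
    read_voc,
    simulate_20x,
    write_voc,
)

tmp = Path(tempfile.mkdtemp())

# one-line dataset: PNGs, VOC XML boxes, mask PNGs, CSV manifest
manifest = generate_dataset(5, SceneSpec(seed=2), tmp / "ds")
print(f"dataset manifest: {manifest}")
print(manifest.read_text().splitlines()[0])

# VOC round trip (files are 1-based inclusive, memory is 0-based half-open)
boxes = [StomaBox(10, 20, 44, 33)]
write_voc(boxes, {"filename": "x.png", "width": 256, "height": 256}, tmp / "x.xml")
print(f"VOC round trip: {read_voc(tmp / 'x.xml')[0]}")

# five mutually exclusive folds
folds = make_folds([f"img_{i}" for i in range(20)], k=5, seed=0)
print(f"fold sizes: {[sum(1 for v in folds.values() if v == f) for f in range(1, 6)]}")

# offline augmentation: original + 45/90/135 degree rotations
mic = Micrograph(np.full((128, 128, 3), 200, np.uint8), image_id="demo")
augmented = offline_augment([(mic, boxes)])
print(f"offline augmentation: 1 image -> {len(augmented)} images")

# x20 simulation: crop 680x512 from a 1360x1024 frame, cubic x2 upsample
big = Micrograph(np.random.default_rng(0).integers(0, 256, (1024, 1360, 3)).astype(np.uint8))
x20, _ = simulate_20x(big, [])
print(f"x20 simulation: {big.width}x{big.height} -> {x20.width}x{x20.height} ({x20.magnification.value})")
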