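"""Shared fixtures: a bank of synthetic scenes and session-trained models.

The heavy fixtures (trained detector/segmenter) are session-scoped so the
training cost is paid once and shared by the training-contract, pipeline and
acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import settings

from stomx import (
    DetectorConfig,
    SceneSpec,
    SegConfig,
    generate_scene,
    train_detector,
    train_segmenter,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

N_TRAIN = 40
N_HELDOUT = 10


@pytest.fixture(scope="session")
def scene_bank():
    """50 synthetic scenes at the generator's default study conditions."""
    return [generate_scene(SceneSpec(seed=s)) for s in range(N_TRAIN + N_HELDOUT)]


@pytest.fixture(scope="session")
def train_scenes(scene_bank):
    return scene_bank[:N_TRAIN]


@pytest.fixture(scope="session")
def heldout_scenes(scene_bank):
    return scene_bank[N_TRAIN:]


@pytest.fixture(scope="session")
def trained_segmenter(train_scenes):
    pairs = [(mic, truth.wall_mask) for mic, truth in train_scenes]
    return train_segmenter(pairs, SegConfig.small(seed=0))


@pytest.fixture(scope="session")
def trained_detector(train_scenes):
    samples = [(mic, truth.stoma_boxes) for mic, truth in train_scenes]
    return train_detector(samples, DetectorConfig.small(seed=0))


def flood_fill_count(mask: np.ndarray, connectivity: int = 4):
    """Independent iterative flood-fill domain counter (oracle).

    Deliberately naive: explicit stack, pure python, no scipy.  Returns
    (n_domains, sorted list of domain areas).
    """
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    seen = np.zeros((h, w), bool)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    areas = []
    for y0 in range(h):
        for x0 in range(w):
            if not mask[y0, x0] or seen[y0, x0]:
                continue
            stack = [(y0, x0)]
            seen[y0, x0] = True
            area = 0
            while stack:
                y, x = stack.pop()
                area += 1
                for dy, dx in steps:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            areas.append(area)
    return len(areas), sorted(areas)
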