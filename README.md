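# stomx — automatic stomatal-index measurement for leaf-epidermis micrographs

The stomatal index, **SI = 100·S/(S+E)** for S stomata and E epidermal
cells in a field of view, is a developmentally stable trait of the leaf
epidermis — far more stable than stomatal density, which drifts with cell
expansion and magnification.  Measuring it has traditionally meant counting
hundreds of cells per micrograph by hand.  `stomx` automates the whole
measurement for researchers in plant phenotyping and physiology:

- an **anchor-based convolutional detector** finds and counts stomata
  (detections with confidence > 0.9 count);
- a **U-Net-style segmenter** predicts the epidermal cell network, and a
  morphological chain — bilateral filtering, binarization, opening,
  connected-domain labeling, 1/10-mean-area filtering — counts the cells;
- the **index pipeline** composes the two counts into SI (and stomatal
  density when the field of view is known);
- a **metric suite** implements every statistic used to evaluate such
  pipelines: AP at IoU > 0.6, Dice, counting accuracy `1−|A−M|/M`,
  counting precision `log₁₀(M/A)`, identity-line R²/RMSE, CV, Pearson r,
  paired t-tests, and average running time;
- a **synthetic micrograph generator** renders grass-like epidermis scenes
  (elongated cells, dumbbell stomata with subsidiary cells, trichomes,
  noise) with exact ground truth, so every stage is trainable and testable
  at desk scale without microscope data.

The networks run on a compact, deterministic numpy convolution engine
bundled with the package; training the desk-scale models takes minutes on a
single CPU.  Annotations use standard formats: Pascal VOC XML for boxes,
0/255 PNG for wall masks, CSV manifests, YAML run configs.

## Worked example

```python
from stomx import SceneSpec, generate_scene

spec = SceneSpec(seed=1, target_cell_count=40, target_stomatal_index_pct=15.0)
micrograph, truth = generate_scene(spec)
print(truth.n_stomata, truth.n_epidermal_cells, f"{truth.stomatal_index_pct:.2f}%")
```

prints `6 31 16.22%`: the scene carries 6 stomata and 31 epidermal cells,
so its true index is 100·6/37 = 16.22%.  Training both models and measuring
held-out scenes (`python examples/03_train_and_measure.py`, a few minutes on
one CPU) ends with:

```
scene_40: stomata 5 (truth 6), cells 34 (truth 34), index 12.82% (truth 15.00%)
scene_41: stomata 6 (truth 6), cells 34 (truth 34), index 15.00% (truth 15.00%)
...
scene_49: stomata 6 (truth 6), cells 34 (truth 34), index 15.00% (truth 15.00%)
mean stomata counting accuracy: 0.933
mean stomatal-index accuracy:  0.929
average running time: 0.23 s/image
```

i.e. on ten held-out synthetic micrographs the automatic stomata count is
within 6.7% of truth on average and the measured index within 7.1%, with
the epidermal-cell count nearly exact.  The `examples/` directory holds one
short script per capability (scene generation, mask counting, training and
measurement, evaluation metrics, annotation protocols).

A thin CLI mirrors the workflow for shell use:

```bash
stomx generate --config run.yaml      # synthetic dataset + manifest
stomx train-detector --config run.yaml
stomx train-segmenter --config run.yaml
stomx run --config run.yaml           # results.csv + timing report
stomx evaluate --config run.yaml      # metrics.json
```

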