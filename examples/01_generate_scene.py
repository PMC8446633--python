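"""Generate one synthetic epidermis micrograph and inspect its ground truth.

The scene emulates a grass-leaf abaxial epidermis: elongated pavement cells,
dumbbell-shaped stomata with darker subsidiary tissue, occasional trichomes,
Gaussian illumination noise.  The truth record carries the exact stoma boxes,
the wall mask and the counts the rest of the pipeline is scored against.
"""

from stomx import SceneSpec, generate_scene

spec = SceneSpec(seed=1, target_cell_count=40, target_stomatal_index_pct=15.0)
micrograph, truth = generate_scene(spec)

print(f"image: {micrograph.width}x{micrograph.height}, id={micrograph.image_id}")
print(f"stomata: {truth.n_stomata}")
print(f"epidermal cells: {truth.n_epidermal_cells}")
print(f"stomatal index: {truth.stomatal_index_pct:.2f}%")
print(f"first stoma box: {truth.stoma_boxes[0]}")
# The index is 100*S/(S+E); the generator targets 15% and hits it up to the
# integer rounding of how many cells become stomata.
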