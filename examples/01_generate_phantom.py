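"""Generate one random labeled tissue phantom and inspect it.

Random convex polyhedra and extruded ASCII letters are dropped into a
homogeneous background; overlaps get their own compound labels, and every
label receives tissue-like random optical properties.
"""

import numpy as np

from mcdn import random_phantom

rng = np.random.default_rng(40)
phantom = random_phantom(rng, grid_shape=(32, 32, 32), voxel_size=1.0)

print(f"grid shape: {phantom.grid_shape}, voxel size {phantom.voxel_size} mm")
labels, counts = np.unique(phantom.label_grid, return_counts=True)
for lbl, cnt in zip(labels, counts):
    p = phantom.properties[int(lbl)]
    print(f"label {lbl}: {cnt:6d} voxels  "
          f"mua={p.mua:.4f}/mm mus={p.mus:.2f}/mm g={p.g:.3f} n={p.n:.2f}")
print("Each label is one tissue type; label 0 is the background. Compound "
      "labels (sums of powers of two) mark regions where inclusions overlap.")
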