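"""Voxelwise sign-flip permutation testing with familywise error control.

Plants a known effect corridor in paired difference maps and shows that the
max-statistic test finds it at the right location while keeping false
positives below the familywise alpha.
"""

import numpy as np

from striocon import voxelwise_permutation_test
from striocon.core import VolumeGrid

grid = VolumeGrid(shape=(8, 8, 8), affine=np.eye(4))
rng = np.random.default_rng(0)

corridor = np.zeros(grid.shape, dtype=bool)
corridor[3:5] = True

diffs = rng.normal(0, 1, (16, 8, 8, 8))
diffs[:, corridor] += 2.0  # striosome-bound density exceeds matrix-bound here

result = voxelwise_permutation_test(diffs, grid, n_permutations=1000,
                                    alpha=0.025, rng_seed=1)
sig_pos, sig_neg = result.significant_mask_per_direction
print(f"permutations: {result.n_permutations} "
      f"({'exhaustive' if result.exhaustive else 'sampled'})")
print(f"corridor voxels detected: {sig_pos[corridor].mean():.1%}")
print(f"false positives outside the corridor: {sig_pos[~corridor].mean():.2%}")
print(f"opposite-direction voxels: {int(sig_neg.sum())}")
# The max-statistic null distribution controls the probability of any false
# positive voxel across the whole volume at the per-direction alpha.
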