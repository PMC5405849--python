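"""Build the super-region hierarchy: supervoxels and megavoxels.

Supervoxels are compact ~1000-voxel regions that follow intensity
boundaries; megavoxels merge similar adjacent supervoxels into a handful
of large regions.  Both are exact covers of the voxel grid, so they can be
annotated instead of single voxels.
"""

import numpy as np

import surseg as ss

v, gt = ss.make_two_phase((40, 40, 40), seed=0)
channel = ss.gaussian(v, 1.0)

p = ss.slic_supervoxels(channel)  # default 10x10x10 seed spacing
print(f"{p.K} supervoxels, mean size {v.data.size / p.K:.0f} voxels")
print(f"boundary recall vs true phase boundary: "
      f"{ss.boundary_recall(p.labels, gt):.3f} (1.0 = every true boundary "
      "voxel is within 2 voxels of a supervoxel boundary)")

g = ss.build_region_graph(p.labels, connectivity=6)
print(f"region adjacency graph: {g.n_nodes} nodes, {len(g.edges)} edges, "
      f"max shared boundary {g.boundary_counts.max()} voxel pairs")

fs = ss.FeatureStack(shape=v.shape)
fs.add("gauss", channel)
desc = ss.supervoxel_mean(fs, p)
mv = ss.megavoxels(p, desc.X, similarity_threshold=0.5)
print(f"megavoxels: {mv.M} (the two intensity phases merge into one "
      "megavoxel each)")
sizes = np.bincount(mv.resolve(p).ravel())
print(f"megavoxel sizes: {sizes.tolist()} voxels (sum = {sizes.sum()})")
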