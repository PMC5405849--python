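"""Parent-constrained segmentation with a label hierarchy.

Large regions (nucleus vs. the rest) are segmented first with model
training; the child label (nucleolus) is then painted through a finer
supervoxel partition and constrained to the parent's segmentation, so
child voxels can never leak outside the nucleus.
"""

import numpy as np

import surseg as ss
from surseg.labels import constrain_to_parent, paint
from surseg.synthetic import NUCLEOLUS, NUCLEUS

v, gt = ss.make_phantom((64, 64, 64), snr=5.0, seed=1)

hierarchy = ss.LabelHierarchy()
hierarchy.add(0, "cell-context", "#888888")
hierarchy.add(1, "nucleus", "#3366ff")
hierarchy.add(2, "nucleolus", "#ff3333", parent=1)

# stage 1: nucleus (incl. nucleoli) vs everything else, from 1% strokes
parent_gt = np.isin(gt, [NUCLEUS, NUCLEOLUS]).astype(np.int32)
ann = ss.sparse_annotations(parent_gt, fraction=0.01, seed=1)
res = ss.segment_volume(v, ann, seed=0)
parent_mask = res.voxel_labels == 1
print(f"nucleus mask: {parent_mask.sum()} voxels (truth {parent_gt.sum()}), "
      f"accuracy {np.mean((res.voxel_labels == 1) == (parent_gt == 1)):.3f}")

# stage 2: nucleoli are far smaller than the default 10^3 supervoxels, so
# the child level uses a finer partition and the region-painting workflow:
# one pen stroke through a nucleolus annotates every supervoxel it touches.
fine = ss.slic_supervoxels(ss.gaussian(v, 1.0), seed_spacing=(4, 4, 4))
inside = constrain_to_parent(parent_mask, fine)
print(f"fine supervoxels inside the nucleus: {inside.sum()} / {fine.K} "
      "(majority-inside rule)")

centroid = np.round(np.argwhere(gt == NUCLEOLUS).mean(axis=0)).astype(int)
stroke = [centroid + (0, 0, d) for d in (-1, 0, 1)]
child_ann = ss.AnnotationVolume.empty(gt.shape)
paint(child_ann, stroke, "supervoxel", 2, hierarchy, partition=fine)
painted = child_ann.labels == 2
print(f"pen stroke of {len(stroke)} voxels annotated {painted.sum()} voxels "
      "through supervoxels")

# the hierarchy clips the child annotation to the parent segmentation
child_mask = painted & parent_mask
overlap = (child_mask & (gt == NUCLEOLUS)).sum() / max(child_mask.sum(), 1)
print(f"after parent constraint: {child_mask.sum()} nucleolus voxels, "
      f"{overlap:.2f} of them true nucleolus; outside-parent voxels kept: "
      f"{int((painted & ~parent_mask).sum())} -> clipped to 0")
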