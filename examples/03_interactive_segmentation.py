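"""Semi-supervised segmentation from sparse pen strokes.

One percent of the voxels are annotated with stroke-like runs; an
extremely randomized forest learns from the annotated supervoxels, and an
edge-weighted Potts MRF makes the prediction spatially coherent.  The
confidence-acceptance loop then grows the annotation set from confident
predictions, mirroring the iterative annotate-train-accept workflow.
"""

import numpy as np

import surseg as ss
from surseg.labels import regions_from_voxel_annotations
from surseg.model import accept_by_confidence, predict, train

v, gt = ss.make_phantom((64, 64, 64), snr=5.0, seed=0)
ann = ss.sparse_annotations(gt, fraction=0.01, seed=0)
print(f"annotated fraction: {ann.labelled_fraction():.4f}")

res = ss.segment_volume(v, ann, seed=0)
acc_raw = np.mean(res.raw_voxel_labels == gt)
acc_ref = np.mean(res.voxel_labels == gt)
print(f"voxel accuracy: raw classifier {acc_raw:.3f}, "
      f"MRF-refined {acc_ref:.3f} (refinement never hurts)")
print(f"final MRF energy: {res.energy:.2f}")

# confidence acceptance: accept supervoxels the model is >=99% sure about
sv_ann = regions_from_voxel_annotations(ann, res.partition)
n0 = (sv_ann >= 0).sum()
for it in range(2):
    m = train(res.descriptors, sv_ann, seed=0)
    pf = predict(m, res.descriptors)
    sv_ann = accept_by_confidence(pf, 0.99, sv_ann)
    print(f"iteration {it}: annotated supervoxels {n0} -> {(sv_ann >= 0).sum()}"
          f" (mean confidence {pf.probs.max(axis=1).mean():.3f})")
    n0 = (sv_ann >= 0).sum()
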