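"""Generate a synthetic cellular volume and explore feature channels.

The phantom mimics a low-SNR tomogram: a cell with nucleus, nucleoli and
organelles over background, plus Gaussian noise.  Feature channels enhance
different aspects of it — Gaussian smoothing for region extraction, TV
denoising for piecewise-smooth classification features, gradient magnitude
for boundaries.
"""

import numpy as np

import surseg as ss

v, gt = ss.make_phantom(shape=(64, 64, 64), snr=5.0, seed=0)
print(f"phantom {v.shape}, intensity range "
      f"[{v.data.min():.2f}, {v.data.max():.2f}]")
for code, name in ss.synthetic.PHASE_NAMES.items():
    print(f"  phase {code} ({name:10s}): {(gt == code).sum():7d} voxels")

gauss = ss.gaussian(v, 1.0)
tv = ss.tv_denoise(v.data, weight=0.1)
gm = ss.gradient_magnitude(v, 1.0)

# denoisers shrink the noise: within-phase variance drops
for name, ch in [("raw", v.data), ("gaussian", gauss), ("tv", tv)]:
    var = np.mean([ch[gt == c].var() for c in np.unique(gt)])
    print(f"{name:9s} mean within-phase variance: {var:.4f}")
print(f"gradient magnitude is largest near phase boundaries: "
      f"boundary mean {gm[np.abs(np.diff(gt, axis=0, prepend=0)) > 0].mean():.3f} "
      f"vs interior mean {gm.mean():.3f}")
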