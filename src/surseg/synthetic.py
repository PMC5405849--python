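"""Synthetic phantoms emulating low-SNR cellular tomograms.

The phantom is a piecewise-smooth cell: background, cell body (cytoplasm),
an ellipsoidal nucleus, nucleoli inside the nucleus and non-overlapping
ellipsoidal organelles in the cytoplasm, each phase with a distinct mean
intensity.  Within-phase intensity varies smoothly but stays within half
the inter-class gap, so in the noiseless limit the phases are exactly
recoverable by thresholding.  Gaussian noise is added with

    sd = (minimum gap between adjacent class means) / SNR,

i.e. at SNR 5 the class means sit five noise standard deviations apart.
An optional anisotropic z-blur mimics missing-wedge elongation from
limited-tilt tomography.  Ground truth is returned voxel-aligned, and a
stroke sampler turns it into sparse pen-like annotations so the whole
segmentation pipeline is testable with no real data.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi

from .io_volume import Volume
from .labels import AnnotationVolume

__all__ = [
    "make_phantom",
    "make_two_phase",
    "sparse_annotations",
    "PHASE_NAMES",
]

BACKGROUND, CYTOPLASM, ORGANELLE, NUCLEUS, NUCLEOLUS = range(5)
PHASE_NAMES = {BACKGROUND: "background", CYTOPLASM: "cytoplasm",
               ORGANELLE: "organelle", NUCLEUS: "nucleus",
               NUCLEOLUS: "nucleolus"}

# class mean intensities, ordered so adjacent phases differ by >= 1.0
_PHASE_MEANS = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
_MIN_GAP = 1.0


def _ellipsoid_mask(shape, centre, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, centre, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def make_phantom(shape=(64, 64, 64), n_organelles: int = 6, snr: float = 5.0,
                 seed: int = 0, missing_wedge: bool = False
                 ) -> tuple[Volume, np.ndarray]:
    """Generate a cellular phantom volume and its ground-truth label grid.

    Parameters
    ----------
    shape:
        Grid extents ``(nz, ny, nx)``, each at least 32.
    n_organelles:
        Number of ellipsoidal organelles placed in the cytoplasm without
        overlap; if placement fails after bounded retries, fewer are placed
        with a warning.
    snr:
        Minimum class-mean gap divided by the noise standard deviation.
        ``np.inf`` gives the noiseless limit.
    missing_wedge:
        Apply an extra z-axis Gaussian blur to the noiseless signal,
        mimicking the anisotropic elongation of limited-tilt tomography.

    Returns the volume and an integer label grid using the phase codes
    ``BACKGROUND .. NUCLEOLUS`` (see :data:`PHASE_NAMES`).
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 32 for s in shape):
        raise ValueError("phantom shape must be at least 32 on every axis")
    if n_organelles < 0:
        raise ValueError("n_organelles must be >= 0")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    gt = np.full(shape, BACKGROUND, dtype=np.int32)

    centre = np.array([nz, ny, nx]) / 2.0
    cell_axes = np.array([nz, ny, nx]) * rng.uniform(0.38, 0.44, size=3)
    cell = _ellipsoid_mask(shape, centre, cell_axes)
    gt[cell] = CYTOPLASM

    nuc_centre = centre + rng.uniform(-0.05, 0.05, size=3) * np.array(shape)
    nuc_axes = cell_axes * rng.uniform(0.42, 0.5, size=3)
    nucleus = _ellipsoid_mask(shape, nuc_centre, nuc_axes) & cell
    gt[nucleus] = NUCLEUS

    # one or two nucleoli well inside the nucleus
    for _ in range(int(rng.integers(1, 3))):
        off = rng.uniform(-0.3, 0.3, size=3) * nuc_axes
        r = max(2.0, float(min(nuc_axes) * rng.uniform(0.2, 0.3)))
        nucleolus = _ellipsoid_mask(shape, nuc_centre + off, (r, r, r)) & nucleus
        gt[nucleolus] = NUCLEOLUS

    cytoplasm_only = cell & ~nucleus
    placed = 0
    occupied = ~cytoplasm_only  # organelles must avoid nucleus/background
    attempts = 0
    max_attempts = 60 * max(n_organelles, 1)
    while placed < n_organelles and attempts < max_attempts:
        attempts += 1
        c = rng.uniform(0.15, 0.85, size=3) * np.array(shape)
        axes = rng.uniform(3.0, 6.0, size=3)
        org = _ellipsoid_mask(shape, c, axes)
        if org.sum() < 8 or (org & occupied).any():
            continue
        gt[org] = ORGANELLE
        occupied |= ndi.binary_dilation(org)  # keep organelles separated
        placed += 1
    if placed < n_organelles:
        warnings.warn(f"placed only {placed}/{n_organelles} organelles "
                      "without overlap")

    signal = _PHASE_MEANS[gt].astype(np.float64)
    # smooth within-phase variation, bounded below half the class gap so the
    # noiseless phantom remains exactly thresholdable
    texture = ndi.gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    peak = np.abs(texture).max()
    if peak > 0:
        signal = signal + (0.3 * _MIN_GAP) * texture / peak
    if missing_wedge:
        signal = ndi.gaussian_filter1d(signal, sigma=2.0, axis=0, mode="reflect")
    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive")
        sd = _MIN_GAP / float(snr)
        signal = signal + rng.normal(0.0, sd, size=shape)
    return Volume(data=signal.astype(np.float32)), gt


def make_two_phase(shape=(40, 40, 40), radius_frac: float = 0.3,
                   seed: int = 0) -> tuple[Volume, np.ndarray]:
    """Noiseless two-phase phantom: a bright ellipsoid in dark background.

    Used to probe supervoxel boundary adherence against a known boundary.
    """
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)
    centre = np.array(shape) / 2.0 + rng.uniform(-2, 2, size=3)
    axes = np.array(shape) * radius_frac * rng.uniform(0.9, 1.1, size=3)
    gt = _ellipsoid_mask(shape, centre, axes).astype(np.int32)
    signal = np.where(gt > 0, 1.0, 0.0)
    return Volume(data=signal.astype(np.float32)), gt


def sparse_annotations(gt: np.ndarray, fraction: float = 0.01,
                       seed: int = 0, max_run: int = 15) -> AnnotationVolume:
    """Sample stroke-like sparse annotations from a ground-truth grid.

    For every class, pen-stroke-like straight runs of voxels are drawn
    inside the class until about ``fraction`` of the class's voxels is
    labelled (never more).  Classes with no voxels are skipped with a
    warning.  ``fraction`` must lie in ``(0, 0.1]`` — annotations are
    sparse by design.
    """
    if not (0.0 < fraction <= 0.1):
        raise ValueError("fraction must lie in (0, 0.1]")
    gt = np.asarray(gt)
    rng = np.random.default_rng(seed)
    ann = AnnotationVolume.empty(gt.shape)
    shape = np.array(gt.shape)
    for lab in np.unique(gt):
        in_class = np.argwhere(gt == lab)
        n_class = in_class.shape[0]
        if n_class == 0:
            warnings.warn(f"class {lab} has no voxels; skipped")
            continue
        target = max(1, int(round(fraction * n_class)))
        labelled = 0
        attempts = 0
        while labelled < target and attempts < 50 * target:
            attempts += 1
            start = in_class[rng.integers(n_class)]
            axis = int(rng.integers(3))
            step = np.zeros(3, dtype=np.int64)
            step[axis] = 1 if rng.random() < 0.5 else -1
            pos = start.copy()
            for _ in range(int(rng.integers(3, max_run + 1))):
                if labelled >= target:
                    break
                if (pos < 0).any() or (pos >= shape).any():
                    break
                z, y, x = pos
                if gt[z, y, x] != lab:
                    break
                if ann.labels[z, y, x] < 0:
                    ann.labels[z, y, x] = lab
                    ann.provenance[z, y, x] = 1  # manual stroke
                    labelled += 1
                pos = pos + step
    return ann
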