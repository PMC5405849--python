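"""Denoising and textural feature channels for 3D volumes.

Every filter maps a volume to one or more channels of the same shape.  A
:class:`FeatureStack` keeps the named channels together with the parameters
that produced them, so any channel can be recomputed deterministically.

Two denoisers are provided: Gaussian smoothing (over-smooths but is well
suited to super-region extraction) and total-variation denoising (preserves
strong edges, splitting the volume into piecewise-smooth regions, better for
classification features).  The textural filters — Gaussian derivatives,
difference/Laplacian of Gaussians, gradient magnitude, Hessian and
structure-tensor eigenvalues — enhance boundaries, blobs and oriented
structure in low-contrast tomographic data.

All filters use reflect padding at the volume boundary and return float32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.restoration import denoise_tv_chambolle

__all__ = [
    "FeatureStack",
    "gaussian",
    "tv_denoise",
    "gaussian_derivative",
    "difference_of_gaussians",
    "laplacian_of_gaussian",
    "gradient_magnitude",
    "hessian_eigenvalues",
    "structure_tensor_eigenvalues",
    "invariant_response",
    "compute_channel",
]

_MODE = "reflect"


def _as_float(v) -> np.ndarray:
    # filters run in float64 for accuracy; channels are stored as float32
    data = v.data if hasattr(v, "data") and not isinstance(v, np.ndarray) else v
    return np.asarray(data, dtype=np.float64)


def _sigma3(sigma) -> tuple[float, float, float]:
    s = np.atleast_1d(np.asarray(sigma, dtype=float))
    if s.size == 1:
        s = np.repeat(s, 3)
    if s.size != 3:
        raise ValueError("sigma must be a scalar or length-3 per-axis sequence")
    if (s < 0).any():
        raise ValueError("sigma must be non-negative")
    return tuple(float(x) for x in s)


@dataclass
class FeatureStack:
    """Ordered, named per-voxel feature channels with their parameters."""

    shape: tuple[int, int, int]
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    params: dict[str, dict] = field(default_factory=dict)

    def add(self, name: str, channel: np.ndarray, params: dict | None = None) -> None:
        channel = np.asarray(channel, dtype=np.float32)
        if channel.shape != tuple(self.shape):
            raise ValueError(f"channel {name!r} shape {channel.shape} != {self.shape}")
        if name in self.channels:
            raise ValueError(f"duplicate channel name {name!r}")
        self.channels[name] = channel
        self.params[name] = dict(params or {})

    @property
    def names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __len__(self) -> int:
        return len(self.channels)


def gaussian(v, sigma) -> np.ndarray:
    """3D Gaussian smoothing; ``sigma=0`` is the identity."""
    data = _as_float(v)
    s = _sigma3(sigma)
    if max(s) == 0:
        return data.copy()
    return ndi.gaussian_filter(data, sigma=s, mode=_MODE).astype(np.float32)


def tv_denoise(v, weight: float = 0.1, max_iter: int = 200,
               tol: float = 1e-4) -> np.ndarray:
    """Total-variation (ROF) denoising via Chambolle's dual projection.

    Larger ``weight`` removes more noise at the cost of flatter regions.
    """
    if weight <= 0:
        raise ValueError("weight must be > 0")
    data = _as_float(v)
    return denoise_tv_chambolle(
        data.astype(np.float64), weight=weight, eps=tol, max_num_iter=max_iter,
    ).astype(np.float32)


def gaussian_derivative(v, sigma, order) -> np.ndarray:
    """Derivative-of-Gaussian response with per-axis orders ``(oz, oy, ox)``."""
    data = _as_float(v)
    s = _sigma3(sigma)
    order = tuple(int(o) for o in np.atleast_1d(order))
    if len(order) == 1:
        order = order * 3
    if any(o < 0 for o in order):
        raise ValueError("derivative orders must be >= 0")
    if sum(order) > 2:
        raise ValueError("total derivative order must be <= 2")
    return ndi.gaussian_filter(data, sigma=s, order=order, mode=_MODE).astype(np.float32)


def difference_of_gaussians(v, sigma1, sigma2) -> np.ndarray:
    """Band-pass response ``G(sigma1) - G(sigma2)`` with ``sigma1 < sigma2``."""
    s1, s2 = _sigma3(sigma1), _sigma3(sigma2)
    if not all(a < b for a, b in zip(s1, s2)):
        raise ValueError("require sigma1 < sigma2 on every axis")
    return gaussian(v, s1) - gaussian(v, s2)


def laplacian_of_gaussian(v, sigma) -> np.ndarray:
    """Sum of unmixed second Gaussian derivatives (trace of the Hessian)."""
    s = _sigma3(sigma)
    if min(s) <= 0:
        raise ValueError("sigma must be > 0")
    data = _as_float(v)
    out = np.zeros_like(data, dtype=np.float32)
    for axis in range(3):
        order = [0, 0, 0]
        order[axis] = 2
        out += ndi.gaussian_filter(data, sigma=s, order=tuple(order), mode=_MODE)
    return out


def gradient_magnitude(v, sigma) -> np.ndarray:
    """Euclidean norm of the three first Gaussian derivatives; non-negative."""
    s = _sigma3(sigma)
    if min(s) <= 0:
        raise ValueError("sigma must be > 0")
    data = _as_float(v)
    acc = np.zeros_like(data, dtype=np.float64)
    for axis in range(3):
        order = [0, 0, 0]
        order[axis] = 1
        g = ndi.gaussian_filter(data, sigma=s, order=tuple(order), mode=_MODE)
        acc += g.astype(np.float64) ** 2
    return np.sqrt(acc).astype(np.float32)


def _hessian_components(data: np.ndarray, s) -> list[np.ndarray]:
    comps = []
    for i in range(3):
        for j in range(i, 3):
            order = [0, 0, 0]
            order[i] += 1
            order[j] += 1
            comps.append(ndi.gaussian_filter(data, sigma=s, order=tuple(order),
                                             mode=_MODE))
    return comps  # zz, zy, zx, yy, yx, xx


def _eigvals_sym3(comps: list[np.ndarray], shape) -> np.ndarray:
    zz, zy, zx, yy, yx, xx = comps
    H = np.empty(shape + (3, 3), dtype=np.float64)
    H[..., 0, 0] = zz
    H[..., 0, 1] = H[..., 1, 0] = zy
    H[..., 0, 2] = H[..., 2, 0] = zx
    H[..., 1, 1] = yy
    H[..., 1, 2] = H[..., 2, 1] = yx
    H[..., 2, 2] = xx
    vals = np.linalg.eigvalsh(H)          # ascending
    return vals[..., ::-1]                # sorted descending by signed value


def hessian_eigenvalues(v, sigma) -> np.ndarray:
    """Eigenvalues of the Gaussian-smoothed Hessian.

    Returns an array of shape ``(3,) + volume.shape`` with eigenvalues
    sorted descending by signed value at every voxel.
    """
    s = _sigma3(sigma)
    if min(s) <= 0:
        raise ValueError("sigma must be > 0")
    data = _as_float(v)
    vals = _eigvals_sym3(_hessian_components(data, s), data.shape)
    return np.moveaxis(vals, -1, 0).astype(np.float32)


def structure_tensor_eigenvalues(v, sigma_grad, sigma_window) -> np.ndarray:
    """Eigenvalues of the windowed gradient outer-product tensor.

    The tensor is positive semi-definite, so all three channels are >= 0;
    a single dominant eigenvalue indicates a locally planar edge.
    """
    sg, sw = _sigma3(sigma_grad), _sigma3(sigma_window)
    if min(sg) <= 0 or min(sw) <= 0:
        raise ValueError("both sigmas must be > 0")
    data = _as_float(v)
    grads = []
    for axis in range(3):
        order = [0, 0, 0]
        order[axis] = 1
        grads.append(ndi.gaussian_filter(data, sigma=sg, order=tuple(order),
                                         mode=_MODE))
    comps = []
    for i in range(3):
        for j in range(i, 3):
            comps.append(ndi.gaussian_filter(grads[i] * grads[j], sigma=sw,
                                             mode=_MODE))
    vals = _eigvals_sym3(comps, data.shape)
    vals = np.clip(vals, 0.0, None)  # PSD up to numerical round-off
    return np.moveaxis(vals, -1, 0).astype(np.float32)


# gamma-normalisation exponents: derivative order of each rotation-invariant base
_INVARIANT_BASES = {
    "gaussian": (gaussian, 0),
    "gradient_magnitude": (gradient_magnitude, 1),
    "laplacian_of_gaussian": (laplacian_of_gaussian, 2),
}


def invariant_response(v, base_filter: str, sigmas,
                       return_argmax: bool = False):
    """Scale-invariant response: max over scales of gamma-normalised filters.

    Each response at scale ``sigma`` is multiplied by ``sigma**order`` (the
    derivative order of the base filter) before the voxelwise maximum of the
    absolute normalised responses is taken.  Rotation invariance comes from
    using rotation-invariant bases only.

    With ``return_argmax=True`` also returns the per-voxel best scale.
    """
    sigmas = list(np.atleast_1d(sigmas).astype(float))
    if not sigmas:
        raise ValueError("need at least one scale")
    if base_filter not in _INVARIANT_BASES:
        raise ValueError(f"unknown base filter {base_filter!r}; "
                         f"choose from {sorted(_INVARIANT_BASES)}")
    fn, order = _INVARIANT_BASES[base_filter]
    best = None
    best_sigma = None
    for s in sigmas:
        resp = np.abs(fn(v, s)) * (s ** order)
        if best is None:
            best = resp
            best_sigma = np.full(resp.shape, s, dtype=np.float32)
        else:
            take = resp > best
            best = np.where(take, resp, best)
            best_sigma[take] = s
    if return_argmax:
        return best.astype(np.float32), best_sigma
    return best.astype(np.float32)


# registry used by the pipeline/CLI to build channels from a parameter record
_CHANNEL_REGISTRY = {
    "gaussian": gaussian,
    "tv": tv_denoise,
    "gaussian_derivative": gaussian_derivative,
    "dog": difference_of_gaussians,
    "log": laplacian_of_gaussian,
    "gradient_magnitude": gradient_magnitude,
    "hessian_eigenvalues": hessian_eigenvalues,
    "structure_tensor_eigenvalues": structure_tensor_eigenvalues,
    "invariant": invariant_response,
}


def compute_channel(v, filter_name: str, **params) -> np.ndarray:
    """Recompute a channel from its stored parameter record (deterministic)."""
    if filter_name not in _CHANNEL_REGISTRY:
        raise ValueError(f"unknown filter {filter_name!r}")
    return _CHANNEL_REGISTRY[filter_name](v, **params)
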