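"""Volume input/output, regions of interest and display contrast.

Volumes are 3D scalar grids indexed ``(z, y, x)`` throughout the package.
Two on-disk formats are supported: MRC2014 (the tomography community's
interchange format) and HDF5.  All derived products (feature channels,
super-region partitions, annotations, predictions) live in a single HDF5
*sidecar* file with a fixed group layout, so a whole analysis is one file::

    /data                       source volume
    /features/<name>            feature channels
    /superregions/supervoxels   supervoxel label grid
    /superregions/megavoxels    megavoxel label grid
    /annotations/<level>        annotation grids (-1 = unlabelled)
    /predictions/labels         refined per-voxel labels
    /predictions/probs          per-region class probabilities
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "Volume",
    "RoI",
    "read_volume",
    "write_volume",
    "clip_to_roi",
    "contrast_limits",
    "Sidecar",
]

# MRC mode -> numpy dtype (MRC2014 standard, subset in common tomography use)
_MRC_MODE_TO_DTYPE = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_DTYPE_TO_MRC_MODE = {np.dtype(v).str: k for k, v in _MRC_MODE_TO_DTYPE.items()}

_MRC_HEADER_SIZE = 1024


@dataclass
class Volume:
    """A 3D scalar grid in fixed ``(z, y, x)`` axis order.

    Parameters
    ----------
    data:
        3D array, any scalar dtype; values must be finite.
    spacing:
        Physical voxel size per axis ``(dz, dy, dx)``.  Carried as metadata
        only; defaults to isotropic unit spacing.
    dtype_info:
        ``(min, max)`` of the source data, recorded at load time.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    dtype_info: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if self.dtype_info is None:
            self.dtype_info = (float(self.data.min()), float(self.data.max()))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class RoI:
    """Half-open bounding cuboid ``[zmin, zmax) x [ymin, ymax) x [xmin, xmax)``."""

    zmin: int
    zmax: int
    ymin: int
    ymax: int
    xmin: int
    xmax: int

    def __post_init__(self) -> None:
        for lo, hi, ax in ((self.zmin, self.zmax, "z"), (self.ymin, self.ymax, "y"),
                           (self.xmin, self.xmax, "x")):
            if not (0 <= lo < hi):
                raise ValueError(f"invalid RoI on axis {ax}: [{lo}, {hi})")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(self.zmin, self.zmax), slice(self.ymin, self.ymax),
                slice(self.xmin, self.xmax))

    def compose(self, inner: "RoI") -> "RoI":
        """RoI expressed in this RoI's local frame -> global frame."""
        return RoI(self.zmin + inner.zmin, self.zmin + inner.zmax,
                   self.ymin + inner.ymin, self.ymin + inner.ymax,
                   self.xmin + inner.xmin, self.xmin + inner.xmax)


def _check_finite(data: np.ndarray, on_nonfinite: str) -> np.ndarray:
    bad = ~np.isfinite(data)
    if not bad.any():
        return data
    if on_nonfinite == "error":
        raise ValueError(
            f"volume contains {int(bad.sum())} non-finite voxels; "
            "pass on_nonfinite='median' to impute them"
        )
    if on_nonfinite == "median":
        fill = float(np.median(data[~bad])) if (~bad).any() else 0.0
        data = data.copy()
        data[bad] = fill
        warnings.warn(f"imputed {int(bad.sum())} non-finite voxels with median {fill}")
        return data
    raise ValueError(f"unknown on_nonfinite policy {on_nonfinite!r}")


def _read_mrc(path: Path) -> np.ndarray:
    raw = path.read_bytes()
    if len(raw) < _MRC_HEADER_SIZE:
        raise ValueError(f"{path}: truncated MRC header")
    # words 1-3: nx(columns), ny(rows), nz(sections); word 4: mode;
    # words 17-19: mapc, mapr, maps (which axis is column/row/section)
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    mapc, mapr, maps = struct.unpack_from("<3i", raw, 64)
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    if mode not in _MRC_MODE_TO_DTYPE:
        raise ValueError(f"{path}: unsupported MRC mode {mode}")
    if min(nx, ny, nz) <= 0:
        raise ValueError(f"{path}: unreadable MRC header (nx,ny,nz)=({nx},{ny},{nz})")
    dtype = np.dtype(_MRC_MODE_TO_DTYPE[mode]).newbyteorder("<")
    offset = _MRC_HEADER_SIZE + nsymbt
    count = nx * ny * nz
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    if data.size != count:
        raise ValueError(f"{path}: MRC data block shorter than header promises")
    # data on disk: sections slowest, columns fastest -> (section, row, column)
    grid = data.reshape(nz, ny, nx)
    if (mapc, mapr, maps) in ((0, 0, 0), (1, 2, 3)):
        return np.ascontiguousarray(grid)  # already (z, y, x)
    perm = {mapc: 2, mapr: 1, maps: 0}  # axis id (1=x,2=y,3=z) -> grid dim
    if sorted(perm) != [1, 2, 3]:
        raise ValueError(f"{path}: invalid axis map ({mapc},{mapr},{maps})")
    # move grid dims so output dims are (z=axis3, y=axis2, x=axis1)
    order = [perm[3], perm[2], perm[1]]
    return np.ascontiguousarray(grid.transpose(order))


def _write_mrc(path: Path, data: np.ndarray) -> None:
    key = np.dtype(data.dtype).str
    if key not in _DTYPE_TO_MRC_MODE:
        data = data.astype(np.float32)
        key = np.dtype(np.float32).str
    mode = _DTYPE_TO_MRC_MODE[key]
    nz, ny, nx = data.shape
    header = bytearray(_MRC_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", header, 28, nx, ny, nz)          # mx, my, mz
    struct.pack_into("<3f", header, 40, float(nx), float(ny), float(nz))  # cell size
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)    # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)             # mapc, mapr, maps
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))        # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(data, dtype=np.dtype(key)).tobytes())


def _resolve_h5_dataset(f: h5py.File, dataset: str | None) -> h5py.Dataset:
    if dataset is not None:
        if dataset not in f:
            raise KeyError(f"dataset {dataset!r} not found")
        obj = f[dataset]
        if not isinstance(obj, h5py.Dataset) or obj.ndim != 3:
            raise ValueError(f"dataset {dataset!r} is not a 3D dataset")
        return obj
    found: list[h5py.Dataset] = []

    def visit(name: str, obj: object) -> None:
        if isinstance(obj, h5py.Dataset) and obj.ndim == 3:
            found.append(obj)

    if "data" in f and isinstance(f["data"], h5py.Dataset) and f["data"].ndim == 3:
        return f["data"]
    f.visititems(visit)
    if not found:
        raise ValueError("no 3D dataset found in HDF5 file (non-3D dataset)")
    return found[0]


def read_volume(path: str | Path, dataset: str | None = None, *,
                on_nonfinite: str = "error") -> Volume:
    """Read an MRC or HDF5 volume into ``(z, y, x)`` order.

    MRC axis conventions are honoured: the on-disk (section, row, column)
    block is permuted according to the header's mapc/mapr/maps words so that
    the returned grid is always indexed ``(z, y, x)``.

    Parameters
    ----------
    path:
        ``.mrc``/``.rec`` or ``.h5``/``.hdf5`` file.
    dataset:
        In-file dataset name (HDF5 only).  Defaults to ``/data`` or the
        first 3D dataset found.
    on_nonfinite:
        ``"error"`` (default) rejects NaN/Inf voxels; ``"median"`` imputes
        them with the median of the finite voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".rec", ".map"):
        data = _read_mrc(path)
        spacing = (1.0, 1.0, 1.0)
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = _resolve_h5_dataset(f, dataset)
            data = ds[()]
            spacing = tuple(ds.attrs.get("spacing", (1.0, 1.0, 1.0)))
    else:
        raise ValueError(f"unsupported format {suffix!r} (expected .mrc or .h5/.hdf5)")
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"non-3D dataset: ndim={data.ndim}")
    data = _check_finite(data, on_nonfinite)
    return Volume(data=data, spacing=spacing)


def write_volume(path: str | Path, v: Volume | np.ndarray,
                 dataset: str = "data") -> None:
    """Write a volume as MRC2014 or HDF5, chosen by file extension."""
    path = Path(path)
    data = v.data if isinstance(v, Volume) else np.asarray(v)
    spacing = v.spacing if isinstance(v, Volume) else (1.0, 1.0, 1.0)
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".rec", ".map"):
        _write_mrc(path, data)
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(dataset, data=data)
            ds.attrs["spacing"] = spacing
    else:
        raise ValueError(f"unsupported format {suffix!r}")


def clip_to_roi(v: Volume, roi: RoI) -> Volume:
    """Extract the sub-volume covered by a half-open bounding cuboid."""
    nz, ny, nx = v.shape
    if roi.zmax > nz or roi.ymax > ny or roi.xmax > nx:
        raise ValueError(f"RoI {roi} out of bounds for shape {v.shape}")
    return Volume(data=v.data[roi.slices].copy(), spacing=v.spacing,
                  dtype_info=v.dtype_info)


def contrast_limits(v: Volume, low_pct: float = 1.0,
                    high_pct: float = 99.0) -> tuple[float, float, bool]:
    """Display contrast limits as data percentiles.

    Returns ``(low, high, degenerate)``; ``degenerate`` is True when the
    two limits coincide (constant volume).  Never mutates the data.
    """
    if not (0.0 <= low_pct < high_pct <= 100.0):
        raise ValueError("require 0 <= low_pct < high_pct <= 100")
    low, high = np.percentile(v.data, [low_pct, high_pct])
    return float(low), float(high), bool(low == high)


class Sidecar:
    """Thin wrapper over the HDF5 sidecar file holding all derived products."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def write(self, name: str, array: np.ndarray,
              attrs: dict | None = None) -> None:
        with h5py.File(self.path, "a") as f:
            if name in f:
                del f[name]
            ds = f.create_dataset(name, data=array)
            for k, val in (attrs or {}).items():
                ds.attrs[k] = val

    def read(self, name: str) -> np.ndarray:
        with h5py.File(self.path, "r") as f:
            return f[name][()]

    def attrs(self, name: str) -> dict:
        with h5py.File(self.path, "r") as f:
            return dict(f[name].attrs)

    def __contains__(self, name: str) -> bool:
        if not self.path.exists():
            return False
        with h5py.File(self.path, "r") as f:
            return name in f
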