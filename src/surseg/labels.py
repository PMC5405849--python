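"""Label hierarchy, annotation volumes and parent-constrained segmentation.

Labels form a forest: child labels (e.g. *nucleolus*) live inside a parent
label (*nucleus*), and training/prediction for children is restricted to
regions lying inside the parent's segmentation.  Annotations are stored as
a per-voxel label grid (``-1`` = unlabelled) plus a provenance code per
labelled voxel recording whether it was painted manually, painted through a
super-region, or accepted from a confident prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .superregions import MegavoxelPartition, SupervoxelPartition

__all__ = [
    "Label",
    "LabelHierarchy",
    "AnnotationVolume",
    "paint",
    "constrain_to_parent",
    "apply_child_predictions",
    "regions_from_voxel_annotations",
    "export_masks",
    "import_masks",
]

PROV_NONE, PROV_MANUAL, PROV_REGION, PROV_ACCEPTED = 0, 1, 2, 3
_PROV_CODES = {"manual": PROV_MANUAL, "region": PROV_REGION,
               "accepted": PROV_ACCEPTED}


@dataclass(frozen=True)
class Label:
    id: int
    name: str
    colour: str = "#808080"
    parent: int | None = None


class LabelHierarchy:
    """Forest of segmentation labels; parent chains define the levels."""

    def __init__(self) -> None:
        self._labels: dict[int, Label] = {}

    def add(self, id: int, name: str, colour: str = "#808080",
            parent: int | None = None) -> Label:
        if id in self._labels:
            raise ValueError(f"duplicate label id {id}")
        if parent is not None and parent not in self._labels:
            raise ValueError(f"parent label {parent} not declared")
        lab = Label(id=id, name=name, colour=colour, parent=parent)
        self._labels[id] = lab
        self._check_forest()
        return lab

    def _check_forest(self) -> None:
        for lab in self._labels.values():
            seen = set()
            cur: int | None = lab.id
            while cur is not None:
                if cur in seen:
                    raise ValueError("label parent graph contains a cycle")
                seen.add(cur)
                cur = self._labels[cur].parent

    def __contains__(self, id: int) -> bool:
        return id in self._labels

    def __getitem__(self, id: int) -> Label:
        return self._labels[id]

    @property
    def ids(self) -> list[int]:
        return list(self._labels)

    def children(self, id: int) -> list[int]:
        return [l.id for l in self._labels.values() if l.parent == id]

    def depth(self, id: int) -> int:
        d, cur = 0, self._labels[id].parent
        while cur is not None:
            d += 1
            cur = self._labels[cur].parent
        return d


@dataclass
class AnnotationVolume:
    """Per-voxel annotations: label grid (-1 unlabelled) + provenance codes."""

    labels: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.provenance is None:
            self.provenance = np.where(self.labels >= 0, PROV_MANUAL,
                                       PROV_NONE).astype(np.int8)
        self.provenance = np.asarray(self.provenance, dtype=np.int8)
        if self.provenance.shape != self.labels.shape:
            raise ValueError("provenance grid must match label grid")

    @classmethod
    def empty(cls, shape: tuple[int, int, int]) -> "AnnotationVolume":
        return cls(labels=np.full(shape, -1, dtype=np.int32),
                   provenance=np.zeros(shape, dtype=np.int8))

    def labelled_fraction(self) -> float:
        return float(np.mean(self.labels >= 0))


def paint(ann: AnnotationVolume, coords, level: str, label: int,
          hierarchy: LabelHierarchy | None = None,
          partition: SupervoxelPartition | None = None,
          megapartition: MegavoxelPartition | None = None) -> AnnotationVolume:
    """Assign a label along a painted voxel path at any hierarchy level.

    At ``level="voxel"`` only the listed voxels change; at
    ``"supervoxel"``/``"megavoxel"`` every voxel of every touched region is
    assigned (the pen tool semantics).  Returns the updated annotation
    volume (modified in place and returned for chaining).
    """
    if hierarchy is not None and label not in hierarchy:
        raise ValueError(f"label {label} not declared in hierarchy")
    coords = np.atleast_2d(np.asarray(coords, dtype=np.int64))
    if coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3) voxel indices (z, y, x)")
    shape = ann.labels.shape
    if (coords < 0).any() or (coords >= np.array(shape)).any():
        raise IndexError("painted coordinates out of bounds")
    zz, yy, xx = coords[:, 0], coords[:, 1], coords[:, 2]
    if level == "voxel":
        ann.labels[zz, yy, xx] = label
        ann.provenance[zz, yy, xx] = PROV_MANUAL
        return ann
    if level in ("supervoxel", "megavoxel"):
        if partition is None:
            raise ValueError("painting at region level needs a partition")
        region_grid = partition.labels
        if level == "megavoxel":
            if megapartition is None:
                raise ValueError("megavoxel painting needs a megavoxel partition")
            region_grid = megapartition.resolve(partition)
        touched = np.unique(region_grid[zz, yy, xx])
        mask = np.isin(region_grid, touched)
        ann.labels[mask] = label
        ann.provenance[mask] = PROV_REGION
        return ann
    raise ValueError(f"unknown level {level!r}")


def constrain_to_parent(parent_mask: np.ndarray,
                        partition: SupervoxelPartition) -> np.ndarray:
    """Boolean region mask: which supervoxels lie inside the parent label.

    A region belongs to the parent when a *strict majority* of its voxels
    is inside the parent mask; ties are broken toward exclusion, keeping
    child segmentations conservative.
    """
    parent_mask = np.asarray(parent_mask, dtype=bool)
    if not parent_mask.any():
        raise ValueError("empty parent mask")
    flat = partition.labels.ravel()
    inside = np.bincount(flat, weights=parent_mask.ravel().astype(np.float64),
                         minlength=partition.K)
    total = np.bincount(flat, minlength=partition.K)
    return inside > 0.5 * total


def apply_child_predictions(parent_labelling: np.ndarray,
                            child_labelling: np.ndarray,
                            region_mask: np.ndarray) -> np.ndarray:
    """Overwrite the parent labelling with child labels inside the parent only.

    Regions outside ``region_mask`` keep the parent labelling unchanged.
    """
    parent_labelling = np.asarray(parent_labelling)
    out = parent_labelling.copy()
    out[region_mask] = np.asarray(child_labelling)[region_mask]
    return out


def regions_from_voxel_annotations(ann: AnnotationVolume,
                                   partition: SupervoxelPartition) -> np.ndarray:
    """Lift voxel annotations to supervoxel annotations by majority vote.

    A supervoxel with no annotated voxel stays unlabelled (-1); otherwise it
    takes the most frequent annotated label among its voxels (ties to the
    lowest label id).
    """
    flat_sv = partition.labels.ravel()
    flat_ann = ann.labels.ravel()
    labelled = flat_ann >= 0
    out = np.full(partition.K, -1, dtype=np.int64)
    if not labelled.any():
        return out
    label_vals = np.unique(flat_ann[labelled])
    counts = np.zeros((partition.K, label_vals.size), dtype=np.int64)
    for j, lab in enumerate(label_vals):
        sel = flat_ann == lab
        counts[:, j] = np.bincount(flat_sv[sel], minlength=partition.K)
    has = counts.sum(axis=1) > 0
    out[has] = label_vals[np.argmax(counts[has], axis=1)]
    return out


def export_masks(label_grid: np.ndarray, label_ids, mode: str = "mask",
                 data: np.ndarray | None = None) -> dict[int, np.ndarray]:
    """Per-label binary masks, or the data zeroed outside each mask."""
    label_grid = np.asarray(label_grid)
    present = set(np.unique(label_grid).tolist())
    out: dict[int, np.ndarray] = {}
    for lab in label_ids:
        if lab not in present and lab >= 0:
            out[int(lab)] = np.zeros(label_grid.shape, dtype=bool)
            continue
        mask = label_grid == lab
        if mode == "mask":
            out[int(lab)] = mask
        elif mode == "masked_data":
            if data is None:
                raise ValueError("masked_data mode needs the data grid")
            out[int(lab)] = np.where(mask, data, 0)
        else:
            raise ValueError(f"unknown export mode {mode!r}")
    return out


def import_masks(masks: dict[int, np.ndarray],
                 shape: tuple[int, int, int]) -> np.ndarray:
    """Recombine per-label binary masks into a label grid (-1 = unlabelled)."""
    out = np.full(shape, -1, dtype=np.int64)
    for lab in sorted(masks):
        m = np.asarray(masks[lab], dtype=bool)
        out[m] = lab
    return out
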