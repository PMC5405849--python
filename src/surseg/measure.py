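"""Per-object morphometry and rule-based object classification.

The *label splitter* workflow: connected objects of a segmentation label
are measured (size, bounding box, centroid, intensity statistics on a
chosen feature channel), simple comparison rules split them into named
classes (e.g. lipid droplets vs. mitochondria by average intensity and
size), and the result is exported as new label grids and CSV tables.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "Rule",
    "RuleSet",
    "object_stats",
    "apply_rules",
    "split_to_labels",
    "export_statistics",
]

_CONNECTIVITY_STRUCTS = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}

_OPS = {"<": operator.lt, "<=": operator.le, ">": operator.gt,
        ">=": operator.ge, "=": operator.eq, "==": operator.eq}

_METRIC_COLUMNS = [
    "object_id", "label", "voxel_count",
    "bbox_zmin", "bbox_zmax", "bbox_ymin", "bbox_ymax", "bbox_xmin", "bbox_xmax",
    "bbox_depth", "bbox_height", "bbox_width",
    "centroid_z", "centroid_y", "centroid_x",
    "bbox_centre_z", "bbox_centre_y", "bbox_centre_x",
    "avg_intensity", "intensity_variance", "intensity_std",
]


@dataclass(frozen=True)
class Rule:
    """One comparison on an object metric, e.g. ``voxel_count >= 8``."""

    metric: str
    comparator: str
    threshold: float

    def __post_init__(self) -> None:
        if self.comparator not in _OPS:
            raise ValueError(f"unknown comparator {self.comparator!r}")

    def evaluate(self, table: pd.DataFrame) -> pd.Series:
        if self.metric not in table.columns:
            raise KeyError(f"metric {self.metric!r} not in object table")
        return _OPS[self.comparator](table[self.metric], self.threshold)


@dataclass
class RuleSet:
    """AND-chain of rules defining one object class."""

    name: str
    rules: list[Rule]

    def __post_init__(self) -> None:
        # reject contradictory bounds on the same metric at parse time
        lo: dict[str, float] = {}
        hi: dict[str, float] = {}
        for r in self.rules:
            if r.comparator in (">", ">="):
                lo[r.metric] = max(lo.get(r.metric, -np.inf), r.threshold)
            elif r.comparator in ("<", "<="):
                hi[r.metric] = min(hi.get(r.metric, np.inf), r.threshold)
        for metric in set(lo) & set(hi):
            if lo[metric] > hi[metric]:
                raise ValueError(
                    f"contradictory rules on {metric!r}: "
                    f"min {lo[metric]} > max {hi[metric]}")

    def matches(self, table: pd.DataFrame) -> pd.Series:
        out = pd.Series(True, index=table.index)
        for r in self.rules:
            out &= r.evaluate(table)
        return out


def object_stats(labels: np.ndarray, label: int, channel: np.ndarray,
                 connectivity: int = 26) -> pd.DataFrame:
    """Measure every connected object of one segmentation label.

    Objects are maximal connected components (default 26-connectivity) of
    the label's mask.  Intensity statistics (mean, variance, standard
    deviation) are computed on ``channel``; position is reported both as
    the intensity-free centroid and as the bounding-box centre.  Rows are
    ordered by descending size, then centroid, and an absent label yields
    an empty table rather than an error.
    """
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    labels = np.asarray(labels)
    channel = np.asarray(channel, dtype=np.float64)
    if channel.shape != labels.shape:
        raise ValueError("channel shape must match label grid")
    mask = labels == label
    if not mask.any():
        return pd.DataFrame(columns=_METRIC_COLUMNS)
    comp, n = ndi.label(mask, structure=_CONNECTIVITY_STRUCTS[connectivity])
    ids = np.arange(1, n + 1)
    counts = ndi.sum_labels(np.ones_like(comp), comp, ids).astype(np.int64)
    means = ndi.mean(channel, comp, ids)
    variances = ndi.variance(channel, comp, ids)
    centroids = np.array(ndi.center_of_mass(mask, comp, ids))
    slices = ndi.find_objects(comp)
    rows = []
    for i, oid in enumerate(ids):
        sl = slices[oid - 1]
        bbox = [(s.start, s.stop) for s in sl]
        rows.append({
            "object_id": int(oid),
            "label": int(label),
            "voxel_count": int(counts[i]),
            "bbox_zmin": bbox[0][0], "bbox_zmax": bbox[0][1],
            "bbox_ymin": bbox[1][0], "bbox_ymax": bbox[1][1],
            "bbox_xmin": bbox[2][0], "bbox_xmax": bbox[2][1],
            "bbox_depth": bbox[0][1] - bbox[0][0],
            "bbox_height": bbox[1][1] - bbox[1][0],
            "bbox_width": bbox[2][1] - bbox[2][0],
            "centroid_z": float(centroids[i][0]),
            "centroid_y": float(centroids[i][1]),
            "centroid_x": float(centroids[i][2]),
            "bbox_centre_z": (bbox[0][0] + bbox[0][1] - 1) / 2.0,
            "bbox_centre_y": (bbox[1][0] + bbox[1][1] - 1) / 2.0,
            "bbox_centre_x": (bbox[2][0] + bbox[2][1] - 1) / 2.0,
            "avg_intensity": float(means[i]),
            "intensity_variance": float(variances[i]),
            "intensity_std": float(np.sqrt(variances[i])),
        })
    df = pd.DataFrame(rows, columns=_METRIC_COLUMNS)
    df = df.sort_values(
        by=["voxel_count", "centroid_z", "centroid_y", "centroid_x"],
        ascending=[False, True, True, True], kind="mergesort",
    ).reset_index(drop=True)
    return df


def apply_rules(table: pd.DataFrame, classes: list[RuleSet]) -> pd.Series:
    """Assign each object to the first matching class (declared order wins).

    Unmatched objects keep their source label, reported as ``None``.
    """
    assignment = pd.Series([None] * len(table), index=table.index, dtype=object)
    for rs in classes:
        m = rs.matches(table) & assignment.isna()
        assignment[m] = rs.name
    return assignment


def split_to_labels(labels: np.ndarray, label: int, table: pd.DataFrame,
                    assignment: pd.Series, class_ids: dict[str, int],
                    connectivity: int = 26) -> np.ndarray:
    """Write rule-based class assignments back as a new label grid.

    Objects without a class keep the source ``label``, so recombining the
    output over all classes reproduces the source mask exactly.
    """
    comp, _ = ndi.label(labels == label,
                        structure=_CONNECTIVITY_STRUCTS[connectivity])
    out = np.asarray(labels).copy()
    for idx, row in table.iterrows():
        cls = assignment[idx]
        if cls is None:
            continue
        out[comp == row["object_id"]] = class_ids[cls]
    return out


def export_statistics(table: pd.DataFrame, path: str | Path,
                      assignment: pd.Series | None = None
                      ) -> tuple[Path, Path]:
    """Write the object table and a per-class summary as CSV (RFC-4180).

    Returns ``(table_path, summary_path)``.  The summary holds object
    count and size quantiles per class; with no assignment every object is
    summarised under its source label.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table = table.copy()
    group = assignment if assignment is not None else table["label"]
    table["class"] = [g if g is not None else "unassigned" for g in group] \
        if assignment is not None else group
    table.to_csv(path, index=False)
    rows = []
    for cls, sub in table.groupby("class"):
        q = sub["voxel_count"].quantile([0.0, 0.25, 0.5, 0.75, 1.0])
        rows.append({
            "class": cls, "n_objects": len(sub),
            "total_voxels": int(sub["voxel_count"].sum()),
            "size_min": q[0.0], "size_q25": q[0.25], "size_median": q[0.5],
            "size_q75": q[0.75], "size_max": q[1.0],
        })
    summary = pd.DataFrame(rows)
    summary_path = path.with_name(path.stem + "_summary.csv")
    summary.to_csv(summary_path, index=False)
    return path, summary_path
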