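"""Workflow orchestration: the full segmentation pipeline in one call.

Two entry points are provided.  :func:`segment_volume` is the in-memory
harness — phantom or real volume in, refined per-voxel labels out —
running feature extraction, supervoxel partitioning, descriptor building,
classifier training on sparse annotations, prediction and MRF refinement
with sensible defaults at every stage.  :func:`run_pipeline` executes a
declarative stage list against an HDF5 sidecar file with content-addressed
caching: each stage's products are stored under its group together with a
hash of its parameters and its upstream hash, so re-running an unchanged
configuration reuses every product byte-for-byte, and changing one stage
invalidates exactly the stages downstream of it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np

from . import descriptors as desc_mod
from . import features as feat_mod
from . import labels as labels_mod
from . import model as model_mod
from . import refine as refine_mod
from . import superregions as sr_mod
from . import synthetic as synth_mod
from .io_volume import Sidecar, Volume, read_volume

__all__ = ["SegmentationResult", "segment_volume", "run_pipeline",
           "PipelineConfigError", "PipelineRuntimeError"]


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration (unknown stage, bad parameter)."""


class PipelineRuntimeError(RuntimeError):
    """A stage failed while executing."""


DEFAULT_CHANNELS = (
    {"name": "gauss1", "filter": "gaussian", "sigma": 1.0},
    {"name": "gauss2", "filter": "gaussian", "sigma": 2.0},
    {"name": "tv", "filter": "tv", "weight": 0.1},
    {"name": "gradmag", "filter": "gradient_magnitude", "sigma": 1.0},
)


@dataclass
class SegmentationResult:
    """Everything the in-memory pipeline computed, for inspection."""

    voxel_labels: np.ndarray
    raw_voxel_labels: np.ndarray
    partition: sr_mod.SupervoxelPartition
    graph: sr_mod.RegionGraph
    descriptors: desc_mod.DescriptorMatrix
    probability_field: model_mod.ProbabilityField
    sv_labelling: np.ndarray
    energy: float
    feature_stack: feat_mod.FeatureStack = None  # type: ignore[assignment]


def build_default_features(v: Volume, channels=DEFAULT_CHANNELS
                           ) -> feat_mod.FeatureStack:
    """Compute a feature stack from a list of channel parameter records."""
    fs = feat_mod.FeatureStack(shape=v.shape)
    for spec in channels:
        spec = dict(spec)
        name = spec.pop("name")
        fname = spec.pop("filter")
        out = feat_mod.compute_channel(v, fname, **spec)
        if out.ndim == 4:  # eigenvalue filters give several channels
            for i in range(out.shape[0]):
                fs.add(f"{name}_{i}", out[i], {"filter": fname, **spec, "ev": i})
        else:
            fs.add(name, out, {"filter": fname, **spec})
    return fs


def segment_volume(v: Volume, ann: labels_mod.AnnotationVolume,
                   channels=DEFAULT_CHANNELS,
                   seed_spacing=sr_mod.DEFAULT_SEED_SPACING,
                   compactness: float = sr_mod.DEFAULT_COMPACTNESS,
                   descriptor: str = "mean", augment: bool = True,
                   classifier: str = "erf", lam: float = 1.0,
                   mrf_method: str = "alpha_expansion",
                   seed: int = 0) -> SegmentationResult:
    """Sparse annotations -> refined dense segmentation, all defaults.

    Stages: feature channels; SLIC supervoxels driven by the first
    (Gaussian-denoised) channel; z-scored supervoxel descriptors with
    neighbour augmentation; ERF training on the supervoxel-lifted
    annotations; probabilistic prediction; MRF refinement; broadcast to
    voxels.
    """
    fs = build_default_features(v, channels)
    sv_channel = fs[fs.names[0]]
    p = sr_mod.slic_supervoxels(sv_channel, seed_spacing=seed_spacing,
                                compactness=compactness)
    g = sr_mod.build_region_graph(p.labels, connectivity=6)
    if descriptor == "mean":
        d = desc_mod.supervoxel_mean(fs, p)
    elif descriptor == "sigmaset":
        d = desc_mod.supervoxel_sigmaset(fs, p)
    elif descriptor == "histogram":
        d = desc_mod.supervoxel_histogram(fs, p, seed=seed)
    elif descriptor == "texton":
        d = desc_mod.supervoxel_textons(fs, p, seed=seed)
    else:
        raise ValueError(f"unknown descriptor {descriptor!r}")
    d = desc_mod.normalise(d, "zscore")
    if augment:
        d = desc_mod.augment_neighbors(d, g)
    sv_ann = labels_mod.regions_from_voxel_annotations(ann, p)
    m = model_mod.train(d, sv_ann, classifier_kind=classifier, seed=seed)
    pf = model_mod.predict(m, d)
    raw_idx = np.argmax(pf.probs, axis=1)
    problem = refine_mod.build_mrf(pf, g, d, lam=lam)
    sv_labelling, e = refine_mod.solve_mrf(problem, method=mrf_method, seed=seed)
    voxel_labels = refine_mod.refine_to_voxels(sv_labelling, p, pf.label_ids)
    raw_voxel = refine_mod.refine_to_voxels(raw_idx, p, pf.label_ids)
    return SegmentationResult(
        voxel_labels=voxel_labels, raw_voxel_labels=raw_voxel, partition=p,
        graph=g, descriptors=d, probability_field=pf,
        sv_labelling=sv_labelling, energy=e, feature_stack=fs)


# ---------------------------------------------------------------------------
# declarative, cached pipeline over an HDF5 sidecar

_KNOWN_STAGES = ("synth", "load", "features", "supervoxels", "megavoxels",
                 "annotate", "train_predict", "refine")


def _param_hash(stage: dict, upstream: str) -> str:
    payload = json.dumps(stage, sort_keys=True, default=str) + "|" + upstream
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _validate(config: dict) -> list[dict]:
    if "stages" not in config or not isinstance(config["stages"], list):
        raise PipelineConfigError("config needs a 'stages' list")
    stages = []
    for i, st in enumerate(config["stages"]):
        if not isinstance(st, dict) or "stage" not in st:
            raise PipelineConfigError(f"stage #{i} needs a 'stage' key")
        if st["stage"] not in _KNOWN_STAGES:
            raise PipelineConfigError(
                f"stage #{i}: unknown stage {st['stage']!r} "
                f"(known: {', '.join(_KNOWN_STAGES)})")
        stages.append(dict(st))
    return stages


def run_pipeline(config: dict, sidecar_path) -> list[dict]:
    """Execute a declarative stage list against an HDF5 sidecar.

    Returns a report: one record per stage with its parameters, hash,
    whether it was served from cache, and its wall time.  Caching is keyed
    on the stage parameters plus the upstream hash, so editing an early
    stage re-runs everything after it while an unchanged config is a
    no-op.
    """
    stages = _validate(config)
    sc = Sidecar(sidecar_path)
    report: list[dict] = []
    upstream = ""
    state: dict = {}
    for st in stages:
        name = st["stage"]
        h = _param_hash(st, upstream)
        upstream = h
        t0 = time.perf_counter()
        cached = _try_cache(sc, name, h, state)
        if not cached:
            try:
                _run_stage(sc, name, st, h, state)
            except (PipelineConfigError, PipelineRuntimeError):
                raise
            except (KeyError, ValueError) as exc:
                raise PipelineConfigError(f"stage {name!r}: {exc}") from exc
            except Exception as exc:  # pragma: no cover - defensive
                raise PipelineRuntimeError(f"stage {name!r} failed: {exc}") from exc
        report.append({"stage": name, "params": st, "hash": h,
                       "cached": cached,
                       "seconds": round(time.perf_counter() - t0, 3)})
    return report


_STAGE_GROUPS = {
    "synth": ["/data", "/annotations/ground_truth"],
    "load": ["/data"],
    "supervoxels": ["/superregions/supervoxels"],
    "megavoxels": ["/superregions/megavoxels"],
    "annotate": ["/annotations/voxel"],
    "train_predict": ["/predictions/probs"],
    "refine": ["/predictions/labels"],
}


def _try_cache(sc: Sidecar, name: str, h: str, state: dict) -> bool:
    """Load a stage's products from the sidecar when the hash matches."""
    paths = _STAGE_GROUPS.get(name)
    if name == "features":
        if "/features_manifest" not in sc or sc.attrs("/features_manifest").get("hash") != h:
            return False
        manifest = [s for s in sc.read("/features_manifest").astype(str)]
        fs = feat_mod.FeatureStack(shape=sc.read("/data").shape)
        for ch in manifest:
            fs.add(ch, sc.read(f"/features/{ch}"))
        state["features"] = fs
        return True
    if not paths:
        return False
    for path in paths:
        if path not in sc or sc.attrs(path).get("hash") != h:
            return False
    _load_state(sc, name, state)
    return True


def _load_state(sc: Sidecar, name: str, state: dict) -> None:
    if name in ("synth", "load"):
        state["volume"] = Volume(data=sc.read("/data"))
        if name == "synth":
            state["gt"] = sc.read("/annotations/ground_truth")
    elif name == "supervoxels":
        labels = sc.read("/superregions/supervoxels")
        attrs = sc.attrs("/superregions/supervoxels")
        state["partition"] = sr_mod.SupervoxelPartition(
            labels=labels, K=int(labels.max()) + 1,
            seed_spacing=tuple(attrs.get("spacing", (10, 10, 10))),
            compactness=float(attrs.get("compactness", 30.0)))
        state["graph"] = sr_mod.build_region_graph(labels, connectivity=6)
    elif name == "megavoxels":
        state["megavoxels"] = sc.read("/superregions/megavoxels")
    elif name == "annotate":
        state["annotations"] = labels_mod.AnnotationVolume(
            labels=sc.read("/annotations/voxel"))
    elif name == "train_predict":
        probs = sc.read("/predictions/probs")
        label_ids = sc.attrs("/predictions/probs")["label_ids"]
        state["probability_field"] = model_mod.ProbabilityField(
            probs=probs, label_ids=np.asarray(label_ids))
    elif name == "refine":
        state["refined"] = sc.read("/predictions/labels")


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise PipelineConfigError(
            f"stage {stage!r} needs the product {key!r} from an earlier stage")
    return state[key]


def _run_stage(sc: Sidecar, name: str, st: dict, h: str, state: dict) -> None:
    params = {k: v for k, v in st.items() if k != "stage"}
    if name == "synth":
        v, gt = synth_mod.make_phantom(
            shape=tuple(params.get("shape", (64, 64, 64))),
            n_organelles=params.get("n_organelles", 6),
            snr=params.get("snr", 5.0), seed=params.get("seed", 0),
            missing_wedge=params.get("missing_wedge", False))
        sc.write("/data", v.data, {"hash": h})
        sc.write("/annotations/ground_truth", gt, {"hash": h})
        state["volume"], state["gt"] = v, gt
    elif name == "load":
        v = read_volume(params["path"], params.get("dataset"))
        sc.write("/data", v.data, {"hash": h})
        state["volume"] = v
    elif name == "features":
        v = _require(state, "volume", name)
        fs = build_default_features(v, params.get("channels", DEFAULT_CHANNELS))
        for ch in fs.names:
            sc.write(f"/features/{ch}", fs[ch], {"hash": h, **{
                k: str(val) for k, val in fs.params[ch].items()}})
        sc.write("/features_manifest", np.array(fs.names, dtype="S"), {"hash": h})
        state["features"] = fs
    elif name == "supervoxels":
        fs = _require(state, "features", name)
        channel = fs[params.get("channel", fs.names[0])]
        p = sr_mod.slic_supervoxels(
            channel, seed_spacing=tuple(params.get("spacing", (10, 10, 10))),
            compactness=params.get("compactness", sr_mod.DEFAULT_COMPACTNESS),
            iterations=params.get("iterations", sr_mod.DEFAULT_ITERATIONS))
        sc.write("/superregions/supervoxels", p.labels,
                 {"hash": h, "spacing": p.seed_spacing,
                  "compactness": p.compactness})
        state["partition"] = p
        state["graph"] = sr_mod.build_region_graph(p.labels, connectivity=6)
    elif name == "megavoxels":
        p = _require(state, "partition", name)
        fs = _require(state, "features", name)
        d = desc_mod.supervoxel_mean(fs, p)
        mp = sr_mod.megavoxels(p, d.X, params.get("threshold", 1.0),
                               min_size=params.get("min_size", 1),
                               graph=state.get("graph"))
        sc.write("/superregions/megavoxels", mp.resolve(p), {"hash": h})
        state["megavoxels"] = mp.resolve(p)
    elif name == "annotate":
        gt = _require(state, "gt", name)
        ann = synth_mod.sparse_annotations(gt, params.get("fraction", 0.01),
                                           seed=params.get("seed", 0))
        sc.write("/annotations/voxel", ann.labels, {"hash": h})
        state["annotations"] = ann
    elif name == "train_predict":
        fs = _require(state, "features", name)
        p = _require(state, "partition", name)
        ann = _require(state, "annotations", name)
        d = desc_mod.normalise(desc_mod.supervoxel_mean(fs, p), "zscore")
        if params.get("augment", True):
            d = desc_mod.augment_neighbors(d, state["graph"])
        sv_ann = labels_mod.regions_from_voxel_annotations(ann, p)
        m = model_mod.train(d, sv_ann,
                            classifier_kind=params.get("classifier", "erf"),
                            seed=params.get("seed", 0))
        pf = model_mod.predict(m, d)
        sc.write("/predictions/probs", pf.probs,
                 {"hash": h, "label_ids": pf.label_ids})
        state["probability_field"] = pf
        state["descriptors"] = d
    elif name == "refine":
        pf = _require(state, "probability_field", name)
        p = _require(state, "partition", name)
        d = state.get("descriptors")
        if d is None:
            fs = _require(state, "features", name)
            d = desc_mod.normalise(desc_mod.supervoxel_mean(fs, p), "zscore")
            d = desc_mod.augment_neighbors(d, state["graph"])
        problem = refine_mod.build_mrf(pf, state["graph"], d,
                                       lam=params.get("lam", 1.0))
        labelling, _ = refine_mod.solve_mrf(
            problem, method=params.get("method", "alpha_expansion"),
            seed=params.get("seed", 0))
        refined = refine_mod.refine_to_voxels(labelling, p, pf.label_ids)
        sc.write("/predictions/labels", refined, {"hash": h})
        state["refined"] = refined
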