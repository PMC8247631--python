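"""End-to-end orchestration: config, classical baseline backend, training
prep and inference flows.

Two flows are assembled from the library modules:

* **training prep**: cluster unannotated images into styles, measure style
  statistics, synthesize style-matched image/mask pairs and (optionally)
  augment them — producing a manifest of the extended training set.
* **inference**: pre-segment each image to estimate the typical nucleus size,
  rescale to the 40 px operating point, segment at the normalized scale, map
  instances back to native resolution, refine with the six-parameter chain,
  and score against ground truth when available.

Segmentation itself is delegated to a :class:`SegmentationBackend`; the
shipped :class:`BaselineBackend` is a deterministic classical segmenter
(Otsu threshold + distance-transform watershed) so the whole pipeline runs on
a CPU with no trained weights.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.transform import resize
from skimage.segmentation import watershed

from . import mask_synthesis, rescale, style_clustering
from .augment import AugmentConfig, augment_sample
from .core_io import InstanceSet, ProbabilityMap, write_image, write_instances
from .metrics import ScoreReport, precision_recall_f1
from .postprocess import PostprocessParams, postprocess_chain

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------


class SegmentationBackend(Protocol):
    """Contract: image in, (instances, optional probability map) out.

    The output canvas must equal the input canvas and instance masks must be
    non-empty.  Any segmenter honoring this contract — classical or neural —
    can drive the pipeline.
    """

    name: str
    version: str

    def segment(self, image: np.ndarray) -> tuple[InstanceSet, ProbabilityMap | None]: ...


def baseline_segment(image: np.ndarray, min_area: int = 15) -> tuple[InstanceSet, ProbabilityMap]:
    """Classical fallback segmenter: Otsu threshold + seeded watershed.

    The probability map is the normalized smoothed foreground score, so the
    refinement chain has a meaningful confidence signal.  Fully deterministic.
    A constant image yields an empty instance set.
    """
    gray = image if image.ndim == 2 else image.mean(axis=2)
    gray = np.asarray(gray, dtype=np.float64)
    if gray.max() - gray.min() < 1e-9:
        return InstanceSet(*gray.shape), ProbabilityMap(np.zeros(gray.shape))
    smooth = ndi.gaussian_filter(gray, sigma=1.0)
    thr = threshold_otsu(smooth)
    # bright-on-dark assumed; flip when foreground is the darker phase
    fg = smooth > thr
    if fg.mean() > 0.5:
        fg = ~fg
    fg = ndi.binary_opening(fg, structure=np.ones((3, 3)))
    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=3, labels=fg, exclude_border=False)
    markers = np.zeros(gray.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers, mask=fg)
    inst = InstanceSet.from_label_image(labels.astype(np.int32))
    keep = [i for i in range(len(inst)) if inst.objects[i].shape[0] >= min_area]
    inst = InstanceSet(inst.height, inst.width, [inst.objects[i] for i in keep]).relabeled()
    score = ndi.gaussian_filter(fg.astype(np.float64), sigma=1.5)
    if score.max() > 0:
        score = score / score.max()
    return inst, ProbabilityMap(score)


@dataclass
class BaselineBackend:
    """The classical CPU backend wrapped in the SegmentationBackend contract."""

    name: str = "baseline-watershed"
    version: str = "1"
    min_area: int = 15

    def segment(self, image: np.ndarray) -> tuple[InstanceSet, ProbabilityMap]:
        return baseline_segment(image, self.min_area)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Validated settings for both pipeline flows (YAML-loadable)."""

    schema_version: int = 1
    target_diameter: float = rescale.TARGET_DIAMETER
    canvas_size: int = rescale.CANVAS_SIZE
    images_per_cluster: int = style_clustering.IMAGES_PER_CLUSTER
    min_cluster_size: int = 2
    per_style: int = mask_synthesis.PER_STYLE
    db_fraction: float = mask_synthesis.DB_FRACTION
    synth_canvas: int = 256
    postprocess: PostprocessParams = field(default_factory=PostprocessParams)
    skip_refinement: bool = False
    per_image_rescale: bool = True
    known_diameter: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_diameter <= 0 or self.canvas_size <= 0 or self.per_style < 0:
            raise ValueError("invalid pipeline configuration")
        if not 0.0 <= self.db_fraction <= 1.0:
            raise ValueError("db_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "postprocess" in raw and isinstance(raw["postprocess"], (list, tuple)):
            vals = raw["postprocess"]
            raw["postprocess"] = PostprocessParams(
                p1=vals[0], p2=vals[1], p3=vals[2], p4=int(vals[3]), p5=int(vals[4]), p6=vals[5]
            )
        raw.update(overrides)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["postprocess"] = list(self.postprocess.as_tuple())
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _stage(name: str):
    """Context manager logging a stage's duration."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            logger.info("stage %s: %.3f s", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


# ---------------------------------------------------------------------------
# Training prep flow
# ---------------------------------------------------------------------------


def run_training_prep(
    images: Sequence[np.ndarray],
    masks: Sequence[InstanceSet] | None,
    cfg: PipelineConfig,
    out_dir: str | Path | None = None,
    backend: SegmentationBackend | None = None,
    renderer: mask_synthesis.StyleRenderer | None = None,
    augment_cfg: AugmentConfig | None = None,
) -> pd.DataFrame:
    """Cluster styles, synthesize style-matched pairs, and build a manifest.

    When ``masks`` is None, rough masks come from the backend's
    pre-segmentation.  Returns the manifest (pair id, style id, objects,
    kind); when ``out_dir`` is given, images/masks/manifest are written there.
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    backend = backend or BaselineBackend()
    with _stage("presegmentation"):
        if masks is None:
            masks = [backend.segment(img)[0] for img in images]
    with _stage("clustering"):
        feats = [style_clustering.extract_features(img) for img in images]
        model = style_clustering.metric_fallback_similarity(feats)
        k = style_clustering.choose_k(len(images), cfg.images_per_cluster)
        clustering = style_clustering.cluster_styles(feats, model, k, seed=cfg.seed)
    usable = style_clustering.filter_small_clusters(clustering, cfg.min_cluster_size)
    with _stage("style statistics"):
        stats = {}
        for c in usable:
            members = clustering.members(c)
            stats[c] = mask_synthesis.style_statistics(
                [masks[i] for i in members], [images[i] for i in members]
            )
    with _stage("shape database"):
        db = mask_synthesis.build_shape_db(list(masks)) if any(len(m) for m in masks) else None
    with _stage("synthesis"):
        pairs = mask_synthesis.generate_training_set(
            stats,
            db,
            per_style=cfg.per_style,
            renderer=renderer,
            canvas=(cfg.synth_canvas, cfg.synth_canvas),
            db_fraction=cfg.db_fraction,
            seed=cfg.seed,
        )
    if augment_cfg is not None:
        with _stage("augmentation"):
            pairs = [
                mask_synthesis.SynthPair(*augment_sample(p.image, p.instances, augment_cfg, seed=cfg.seed + i), p.style_id)
                for i, p in enumerate(pairs)
            ]
    rows = [
        {"pair_id": i, "style_id": p.style_id, "n_objects": len(p.instances), "kind": "synthetic"}
        for i, p in enumerate(pairs)
    ]
    manifest = pd.DataFrame(rows, columns=["pair_id", "style_id", "n_objects", "kind"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, p in enumerate(pairs):
            write_image(p.image, out_dir / f"synth_{i:04d}.png")
            write_instances(p.instances, out_dir / f"synth_{i:04d}_mask.png")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    logger.info("training prep: %d styles used, %d synthetic pairs", len(stats), len(pairs))
    return manifest


# ---------------------------------------------------------------------------
# Inference flow
# ---------------------------------------------------------------------------


@dataclass
class InferenceResult:
    instances: list[InstanceSet]
    report: ScoreReport | None = None
    diameters: list[float] = field(default_factory=list)
    factors: list[float] = field(default_factory=list)


def _map_back(inst: InstanceSet, native_shape: tuple[int, int], factor: float) -> InstanceSet:
    """Map instances segmented at the normalized scale back to native pixels."""
    if abs(factor - 1.0) < 1e-12:
        return inst
    objects, labels = [], []
    for coords, lab in zip(inst.objects, inst.labels):
        mask = np.zeros(inst.shape, dtype=bool)
        mask[coords[:, 0], coords[:, 1]] = True
        m = resize(mask, native_shape, order=0, anti_aliasing=False, preserve_range=True).astype(bool)
        c = np.argwhere(m)
        if c.shape[0]:
            objects.append(c)
            labels.append(lab)
    return InstanceSet(native_shape[0], native_shape[1], objects, labels)


def run_inference(
    images: Sequence[np.ndarray],
    cfg: PipelineConfig,
    backend: SegmentationBackend | None = None,
    ground_truth: Sequence[InstanceSet] | None = None,
) -> InferenceResult:
    """Size-normalized segmentation with optional refinement and scoring.

    Per image: pre-segment, estimate the typical diameter (falling back to
    ``cfg.known_diameter`` when nothing is detected), rescale to the target
    diameter, segment the normalized image, map instances back to native
    resolution, then run the refinement chain on the native-scale probability
    map.  Scoring (when ground truth is given) always happens at native
    resolution so the annotations are never resampled.
    """
    backend = backend or BaselineBackend()
    results: list[InstanceSet] = []
    diameters: list[float] = []
    factors: list[float] = []
    shared_diameter: float | None = None
    if not cfg.per_image_rescale and len(images):
        pre = [backend.segment(img)[0] for img in images]
        est = [rescale.estimate_typical_diameter(p) for p in pre if len(p)]
        shared_diameter = float(np.median(est)) if est else (cfg.known_diameter or cfg.target_diameter)
    for idx, img in enumerate(images):
        t0 = time.perf_counter()
        try:
            native_shape = img.shape[:2]
            pre_inst, _ = backend.segment(img)
            if shared_diameter is not None:
                d = shared_diameter
            elif len(pre_inst):
                d = rescale.estimate_typical_diameter(pre_inst)
            elif cfg.known_diameter:
                d = cfg.known_diameter
            else:
                d = cfg.target_diameter  # nothing detected: assume on-target
            plan = rescale.plan_scale(d, cfg.target_diameter, cfg.canvas_size)
            # rescale the image alone (no instances exist yet at this point)
            factor = plan.factor
            if abs(factor - 1.0) < 1e-12:
                norm_img = img
            else:
                out_shape = (max(8, int(round(native_shape[0] * factor))), max(8, int(round(native_shape[1] * factor))))
                if img.ndim == 3:
                    norm_img = resize(img, out_shape + (img.shape[2],), order=1, anti_aliasing=factor < 1, preserve_range=True)
                else:
                    norm_img = resize(img, out_shape, order=1, anti_aliasing=factor < 1, preserve_range=True)
            inst, prob = backend.segment(norm_img)
            inst = _map_back(inst, native_shape, factor)
            if prob is not None and prob.shape != native_shape:
                prob = ProbabilityMap(resize(prob.values, native_shape, order=1, preserve_range=True))
            if not cfg.skip_refinement and prob is not None:
                inst = postprocess_chain(inst, prob, cfg.postprocess)
            results.append(inst.relabeled())
            diameters.append(d)
            factors.append(factor)
            logger.info(
                "inference image %d: d=%.1f factor=%.2f objects=%d (%.3f s)",
                idx, d, factor, len(inst), time.perf_counter() - t0,
            )
        except Exception as exc:
            raise RuntimeError(f"inference failed on image {idx}: {exc}") from exc
    report = None
    if ground_truth is not None:
        if len(ground_truth) != len(results):
            raise ValueError("ground truth count does not match image count")
        report = precision_recall_f1(list(zip(results, list(ground_truth))))
    return InferenceResult(instances=results, report=report, diameters=diameters, factors=factors)
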