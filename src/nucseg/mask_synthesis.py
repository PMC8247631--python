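"""Style-matched synthetic training pairs: shapes, placement, rendering.

Synthetic masks combine two shape sources — real nucleus patches harvested
into a :class:`ShapeDB`, and a parametric perturbed-ellipse simulator — mixed
roughly 50/50.  Object count, size and spacing are drawn from the empirical
:class:`StyleStats` of a style cluster, so the generated layouts track the
source images.  Rendering a mask into an image is delegated to any object
honoring the :class:`StyleRenderer` contract; the shipped
:class:`BaselineRenderer` samples foreground/background intensities from the
style's empirical distributions (a statistical stand-in at the same interface
where a learned image-to-image translation model can be plugged in).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon
from skimage.measure import regionprops
from skimage.transform import resize

from .core_io import GenerationError, InstanceSet

DB_FRACTION = 0.5
PER_STYLE = 20
MAX_PLACE_RETRIES = 1000


# ---------------------------------------------------------------------------
# Shape database
# ---------------------------------------------------------------------------


@dataclass
class ShapeEntry:
    patch: np.ndarray  # bounding-box-cropped boolean mask
    area: int
    equivalent_diameter: float
    eccentricity: float
    solidity: float


@dataclass
class ShapeDB:
    entries: list[ShapeEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def diameters(self) -> np.ndarray:
        return np.array([e.equivalent_diameter for e in self.entries])


def _describe_patch(patch: np.ndarray) -> ShapeEntry:
    props = regionprops(patch.astype(np.uint8))[0]
    return ShapeEntry(
        patch=patch.astype(bool),
        area=int(props.area),
        equivalent_diameter=float(props.equivalent_diameter_area),
        eccentricity=float(props.eccentricity),
        solidity=float(props.solidity),
    )


def build_shape_db(sets: Sequence[InstanceSet]) -> ShapeDB:
    """Harvest every object of the given instance sets into a shape database.

    Each entry is the object's mask cropped to its bounding box, with shape
    descriptors recomputable from the patch itself.
    """
    entries: list[ShapeEntry] = []
    for s in sets:
        for coords in s.objects:
            r0, c0 = coords.min(axis=0)
            r1, c1 = coords.max(axis=0)
            patch = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
            patch[coords[:, 0] - r0, coords[:, 1] - c0] = True
            entries.append(_describe_patch(patch))
    if not entries:
        raise GenerationError("no objects available to build a shape database")
    return ShapeDB(entries)


# ---------------------------------------------------------------------------
# Parametric shape simulator
# ---------------------------------------------------------------------------


def simulate_shape(
    diameter: float,
    eccentricity: float = 0.0,
    irregularity: float = 0.15,
    seed: int | np.random.Generator = 0,
    n_harmonics: int = 4,
) -> np.ndarray:
    """Perturbed-ellipse nucleus shape: a star-convex boolean patch.

    The radial profile is an ellipse radius modulated by a smooth random
    perturbation built from the first ``n_harmonics`` angular harmonics with
    amplitude proportional to ``irregularity``.  Star-convexity guarantees the
    patch is connected and simply connected.  Deterministic given the seed.
    """
    if diameter < 3:
        raise ValueError("diameter must be at least 3 px")
    if not 0.0 <= eccentricity < 1.0:
        raise ValueError("eccentricity must be in [0, 1)")
    if irregularity < 0:
        raise ValueError("irregularity must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = (diameter / 2.0) / (1.0 - eccentricity**2) ** 0.25
    b = (diameter / 2.0) * (1.0 - eccentricity**2) ** 0.25
    theta = np.linspace(0.0, 2.0 * np.pi, 96, endpoint=False)
    # smooth zero-mean angular perturbation, normalized to unit max amplitude
    pert = np.zeros_like(theta)
    for h in range(1, n_harmonics + 1):
        amp = rng.normal(0.0, 1.0 / h)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        pert += amp * np.cos(h * theta + phase)
    peak = np.abs(pert).max()
    if peak > 1e-12:
        pert = pert / peak
    rot = rng.uniform(0.0, np.pi)
    r_ell = (a * b) / np.sqrt((b * np.cos(theta - rot)) ** 2 + (a * np.sin(theta - rot)) ** 2)
    radius = r_ell * np.clip(1.0 + irregularity * pert, 0.2, None)
    pad = int(np.ceil(radius.max())) + 2
    rows = pad + radius * np.sin(theta)
    cols = pad + radius * np.cos(theta)
    canvas = np.zeros((2 * pad + 1, 2 * pad + 1), dtype=bool)
    rr, cc = polygon(rows, cols, canvas.shape)
    canvas[rr, cc] = True
    coords = np.argwhere(canvas)
    r0, c0 = coords.min(axis=0)
    r1, c1 = coords.max(axis=0)
    return canvas[r0 : r1 + 1, c0 : c1 + 1]


def resample_patch(patch: np.ndarray, target_diameter: float) -> np.ndarray:
    """Rescale a boolean patch so its equivalent diameter hits the target."""
    d = 2.0 * np.sqrt(patch.sum() / np.pi)
    factor = target_diameter / d
    out_shape = (max(1, int(round(patch.shape[0] * factor))), max(1, int(round(patch.shape[1] * factor))))
    out = resize(patch.astype(float), out_shape, order=0, anti_aliasing=False) > 0.5
    if not out.any():
        out = np.ones((1, 1), dtype=bool)
    return out


# ---------------------------------------------------------------------------
# Style statistics
# ---------------------------------------------------------------------------


@dataclass
class StyleStats:
    """Empirical distributions describing one style cluster.

    All fields are raw observation arrays; sampling draws from them directly,
    so sampled values always lie within the observed range.
    """

    object_counts: np.ndarray
    diameters: np.ndarray
    nn_spacing: np.ndarray
    fg_intensity: np.ndarray
    bg_intensity: np.ndarray


def style_statistics(sets: Sequence[InstanceSet], images: Sequence[np.ndarray]) -> StyleStats:
    """Measure the localization and intensity statistics of a style.

    Masks may come from annotations or from a rough pre-segmentation; both
    give usable counts/sizes/spacings for layout synthesis.
    """
    if not sets or len(sets) != len(images):
        raise ValueError("need at least one image with its instance set")
    counts, diams, spacing, fg, bg = [], [], [], [], []
    for s, img in zip(sets, images):
        counts.append(len(s))
        if len(s):
            diams.extend(2.0 * np.sqrt(s.areas() / np.pi))
            cent = s.centroids()
            if len(s) >= 2:
                d = np.sqrt(((cent[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2))
                np.fill_diagonal(d, np.inf)
                spacing.extend(d.min(axis=1))
        gray = img if img.ndim == 2 else img.mean(axis=2)
        fg_mask = np.zeros(s.shape, dtype=bool)
        for i in range(len(s)):
            c = s.objects[i]
            fg_mask[c[:, 0], c[:, 1]] = True
        # subsample intensities to keep stats light
        fg_vals = gray[fg_mask]
        bg_vals = gray[~fg_mask]
        if fg_vals.size:
            fg.extend(fg_vals[:: max(1, fg_vals.size // 2000)])
        if bg_vals.size:
            bg.extend(bg_vals[:: max(1, bg_vals.size // 2000)])
    return StyleStats(
        object_counts=np.asarray(counts, dtype=np.int64),
        diameters=np.asarray(diams, dtype=np.float64),
        nn_spacing=np.asarray(spacing, dtype=np.float64),
        fg_intensity=np.asarray(fg, dtype=np.float64),
        bg_intensity=np.asarray(bg, dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# Mask generation
# ---------------------------------------------------------------------------


def _nearest_db_entry(db: ShapeDB, diameter: float, rng: np.random.Generator) -> ShapeEntry:
    """Pick, among a random subset, the DB shape closest in diameter."""
    n = len(db)
    idx = rng.choice(n, size=min(8, n), replace=False)
    diffs = [abs(db.entries[i].equivalent_diameter - diameter) for i in idx]
    return db.entries[idx[int(np.argmin(diffs))]]


def generate_mask(
    stats: StyleStats,
    db: ShapeDB | None,
    canvas: tuple[int, int],
    db_fraction: float = DB_FRACTION,
    seed: int | np.random.Generator = 0,
    irregularity: float = 0.15,
) -> InstanceSet:
    """Synthesize one non-overlapping instance layout in the given style.

    The object count and per-object diameters are drawn from the style's
    empirical distributions.  Each object comes from the shape database
    (resampled to the drawn diameter) with probability ``db_fraction``,
    otherwise from the parametric simulator.  Placement is rejection sampling:
    a candidate position is accepted when the object does not overlap existing
    ones and its nearest-centroid spacing is no tighter than the smallest
    observed in the style.
    """
    h, w = canvas
    if h < 64 or w < 64:
        raise ValueError("canvas must be at least 64x64")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_obj = int(rng.choice(stats.object_counts))
    min_spacing = float(stats.nn_spacing.min()) if stats.nn_spacing.size else 0.0
    occupied = np.zeros((h, w), dtype=bool)
    objects: list[np.ndarray] = []
    centroids: list[np.ndarray] = []
    for _ in range(n_obj):
        placed = False
        for attempt in range(MAX_PLACE_RETRIES):
            d = float(rng.choice(stats.diameters)) if stats.diameters.size else 12.0
            d = max(d, 3.0)
            use_db = db is not None and len(db) > 0 and rng.random() < db_fraction
            if use_db:
                patch = resample_patch(_nearest_db_entry(db, d, rng).patch, d)
            else:
                ecc = float(rng.uniform(0.0, 0.6))
                patch = simulate_shape(d, ecc, irregularity, rng)
            ph, pw = patch.shape
            if ph >= h or pw >= w:
                continue
            r0 = int(rng.integers(0, h - ph))
            c0 = int(rng.integers(0, w - pw))
            coords = np.argwhere(patch) + np.array([r0, c0])
            cent = coords.mean(axis=0)
            # spacing constraint softens as retries accumulate
            if centroids and min_spacing > 0 and attempt < MAX_PLACE_RETRIES // 2:
                nn = min(np.linalg.norm(cent - c) for c in centroids)
                if nn < min_spacing:
                    continue
            region = occupied[r0 : r0 + ph, c0 : c0 + pw]
            if not (region & patch).any():
                occupied[r0 : r0 + ph, c0 : c0 + pw] |= patch
                objects.append(coords)
                centroids.append(cent)
                placed = True
                break
        if not placed:
            raise GenerationError(f"could not place {n_obj} objects on canvas {canvas}")
    return InstanceSet(h, w, objects)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


class StyleRenderer(Protocol):
    """Contract: turn a binary layout into a synthetic image, same canvas."""

    def render(self, mask: InstanceSet, stats: StyleStats, seed: int) -> np.ndarray: ...


@dataclass
class BaselineRenderer:
    """Statistical renderer: empirical intensities, smoothing, additive noise."""

    smooth_sigma: float = 1.0
    noise_sd: float = 0.02

    def render(self, mask: InstanceSet, stats: StyleStats, seed: int) -> np.ndarray:
        return render_baseline(mask, stats, seed, self.smooth_sigma, self.noise_sd)


def render_baseline(
    mask: InstanceSet,
    stats: StyleStats,
    seed: int | np.random.Generator = 0,
    smooth_sigma: float = 1.0,
    noise_sd: float = 0.02,
) -> np.ndarray:
    """Render a layout by sampling per-pixel intensities from the style.

    Background pixels draw from the background intensity distribution,
    foreground pixels from the foreground one; the field is then smoothed and
    perturbed with Gaussian noise.  Deterministic given the seed.
    """
    if stats.bg_intensity.size == 0 or stats.fg_intensity.size == 0:
        raise ValueError("style statistics lack intensity distributions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = mask.shape
    img = rng.choice(stats.bg_intensity, size=(h, w))
    fg = np.zeros((h, w), dtype=bool)
    for i in range(len(mask)):
        c = mask.objects[i]
        fg[c[:, 0], c[:, 1]] = True
    n_fg = int(fg.sum())
    if n_fg:
        img[fg] = rng.choice(stats.fg_intensity, size=n_fg)
    img = ndi.gaussian_filter(img, sigma=smooth_sigma)
    img = img + rng.normal(0.0, noise_sd, size=(h, w))
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Training-set generation
# ---------------------------------------------------------------------------


@dataclass
class SynthPair:
    image: np.ndarray
    instances: InstanceSet
    style_id: int


def generate_training_set(
    style_stats: dict[int, StyleStats],
    db: ShapeDB | None,
    per_style: int = PER_STYLE,
    renderer: StyleRenderer | None = None,
    canvas: tuple[int, int] = (256, 256),
    db_fraction: float = DB_FRACTION,
    seed: int = 0,
) -> list[SynthPair]:
    """Generate ``per_style`` synthetic image/mask pairs for every style.

    Returns exactly ``per_style * len(style_stats)`` pairs, each tagged with
    its style id; a failure inside one style is re-raised naming that style.
    """
    renderer = renderer or BaselineRenderer()
    out: list[SynthPair] = []
    for style_id in sorted(style_stats):
        stats = style_stats[style_id]
        for i in range(per_style):
            pair_seed = int((seed * 1_000_003 + style_id * 7919 + i) % (2**31))
            try:
                mask = generate_mask(stats, db, canvas, db_fraction, seed=pair_seed)
                img = renderer.render(mask, stats, seed=pair_seed + 1)
            except Exception as exc:
                raise GenerationError(f"style {style_id}: generation failed ({exc})") from exc
            out.append(SynthPair(image=img, instances=mask, style_id=style_id))
    return out
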