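"""Nucleus-size estimation and size-normalizing geometry.

Segmentation networks perform best when the nucleus size is roughly uniform;
the pipeline therefore estimates the typical nucleus diameter of each image
and rescales so the median equivalent diameter lands on a fixed operating
point (40 px by default), then crops or pads to a fixed canvas (512 px).

The "typical size" is the median equivalent-circle diameter
``2*sqrt(area/pi)`` over the detected objects — the median is robust to the
occasional merged blob or debris detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .core_io import InstanceSet

TARGET_DIAMETER = 40.0
CANVAS_SIZE = 512


class EstimationError(ValueError):
    """No objects available to estimate a typical diameter from."""


@dataclass
class ScalePlan:
    estimated_diameter: float
    target_diameter: float
    factor: float
    output_canvas: int = CANVAS_SIZE

    def __post_init__(self) -> None:
        if not np.isfinite(self.factor) or self.factor <= 0:
            raise ValueError("scale factor must be finite and positive")


def equivalent_diameters(s: InstanceSet) -> np.ndarray:
    return 2.0 * np.sqrt(s.areas() / np.pi)


def estimate_typical_diameter(s: InstanceSet) -> float:
    """Median equivalent-circle diameter over the objects of ``s``."""
    if len(s) == 0:
        raise EstimationError(
            "cannot estimate nucleus size from an empty set; "
            "provide a known diameter manually instead"
        )
    return float(np.median(equivalent_diameters(s)))


def plan_scale(d: float, target: float = TARGET_DIAMETER, canvas: int = CANVAS_SIZE) -> ScalePlan:
    """Scaling plan bringing estimated diameter ``d`` to ``target``."""
    if d <= 0:
        raise ValueError("estimated diameter must be positive")
    return ScalePlan(estimated_diameter=float(d), target_diameter=float(target), factor=float(target) / float(d), output_canvas=canvas)


def _scaled_shape(shape: tuple[int, int], factor: float) -> tuple[int, int]:
    return (max(1, int(round(shape[0] * factor))), max(1, int(round(shape[1] * factor))))


def rescale_pair(image: np.ndarray, s: InstanceSet, plan: ScalePlan) -> tuple[np.ndarray, InstanceSet]:
    """Resample an image (bilinear) and its instances (nearest-neighbor).

    Object labels are preserved and no new labels can appear; objects that
    vanish at strong downscaling (area rounding to zero pixels) are dropped.
    """
    factor = plan.factor
    out_shape = _scaled_shape(s.shape, factor)
    if min(out_shape) < 8:
        raise ValueError(f"scaled canvas {out_shape} smaller than 8 px")
    if abs(factor - 1.0) < 1e-12:
        return image.copy(), InstanceSet(s.height, s.width, [c.copy() for c in s.objects], list(s.labels))
    if image.ndim == 3:
        img_out = resize(image, out_shape + (image.shape[2],), order=1, anti_aliasing=factor < 1, preserve_range=True)
    else:
        img_out = resize(image, out_shape, order=1, anti_aliasing=factor < 1, preserve_range=True)
    objects, labels = [], []
    for coords, lab in zip(s.objects, s.labels):
        mask = np.zeros(s.shape, dtype=bool)
        mask[coords[:, 0], coords[:, 1]] = True
        m_out = resize(mask, out_shape, order=0, anti_aliasing=False, preserve_range=True).astype(bool)
        new_coords = np.argwhere(m_out)
        if new_coords.shape[0]:
            objects.append(new_coords)
            labels.append(lab)
    return img_out, InstanceSet(out_shape[0], out_shape[1], objects, labels)


def _tile_starts(extent: int, size: int) -> list[int]:
    """Tile start offsets with 50% overlap, last tile flush with the border."""
    if extent <= size:
        return [0]
    step = size // 2
    starts = list(range(0, extent - size, step))
    starts.append(extent - size)
    return sorted(set(starts))


def crop_or_pad(
    image: np.ndarray, s: InstanceSet, size: int = CANVAS_SIZE
) -> list[tuple[np.ndarray, InstanceSet, tuple[int, int]]]:
    """Cut an image/instance pair into ``size`` x ``size`` tiles.

    Small inputs are zero-padded bottom/right (content anchored top-left);
    large inputs are tiled with 50% overlap so every pixel is covered.
    Objects are clipped at tile borders but keep their labels within a tile.
    Returns (tile image, tile instances, (row offset, col offset)) triples.
    """
    if size <= 0:
        raise ValueError("tile size must be positive")
    h, w = s.shape
    tiles = []
    for r0 in _tile_starts(h, size):
        for c0 in _tile_starts(w, size):
            if image.ndim == 3:
                tile = np.zeros((size, size, image.shape[2]), dtype=image.dtype)
            else:
                tile = np.zeros((size, size), dtype=image.dtype)
            rr = min(h - r0, size)
            cc = min(w - c0, size)
            tile[:rr, :cc] = image[r0 : r0 + rr, c0 : c0 + cc]
            objects, labels = [], []
            for coords, lab in zip(s.objects, s.labels):
                sel = (
                    (coords[:, 0] >= r0)
                    & (coords[:, 0] < r0 + size)
                    & (coords[:, 1] >= c0)
                    & (coords[:, 1] < c0 + size)
                )
                if sel.any():
                    clipped = coords[sel] - np.array([r0, c0])
                    objects.append(clipped)
                    labels.append(lab)
            tiles.append((tile, InstanceSet(size, size, objects, labels), (r0, c0)))
    return tiles


def stitch_tiles(tiles: list[tuple[np.ndarray, InstanceSet, tuple[int, int]]], shape: tuple[int, int]) -> InstanceSet:
    """Paste tile instances back onto the full canvas, last tile wins on overlap.

    Objects are re-labeled consecutively; fragments of one object appearing in
    several tiles stay separate (the caller may merge by connectivity).
    """
    h, w = shape
    label_img = np.zeros((h, w), dtype=np.int32)
    next_lab = 1
    for _, inst, (r0, c0) in tiles:
        for coords in inst.objects:
            rows = coords[:, 0] + r0
            cols = coords[:, 1] + c0
            ok = (rows < h) & (cols < w)
            label_img[rows[ok], cols[ok]] = next_lab
            next_lab += 1
    return InstanceSet.from_label_image(label_img).relabeled()
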