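"""Conventional augmentation operators applied jointly to image/mask pairs.

Geometric operators (crop, rotation, translation) transform the image and
every instance mask identically — masks through nearest-neighbor resampling
so labels survive unchanged; photometric operators (channel swap, histogram
stretch, equalization, inversion, blur, additive noise) touch only the image.
Batch mixing interleaves real and synthetic pairs so that each minibatch
carries a bounded fraction (10-50% by default) of synthetic samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure
from skimage.transform import rotate

from .core_io import InstanceSet

logger = logging.getLogger(__name__)

#: objects reduced below this many pixels by a geometric op are dropped
MIN_OBJECT_PIXELS = 4


@dataclass
class AugmentConfig:
    """Per-operator enable probability and parameter ranges."""

    p_crop: float = 0.5
    crop_fraction: tuple[float, float] = (0.6, 0.9)
    p_channel_swap: float = 0.5
    p_stretch: float = 0.5
    stretch_percentiles: tuple[float, float] = (2.0, 98.0)
    p_equalize: float = 0.25
    p_invert: float = 0.25
    p_rotate: float = 0.5
    rotation_degrees: tuple[float, float] = (0.0, 360.0)
    p_translate: float = 0.5
    translate_fraction: float = 0.2
    p_blur: float = 0.5
    blur_sigma: tuple[float, float] = (0.5, 2.0)
    p_noise: float = 0.5
    noise_sd: tuple[float, float] = (0.01, 0.05)
    synthetic_fraction: tuple[float, float] = (0.10, 0.50)

    def __post_init__(self) -> None:
        for name in ("p_crop", "p_channel_swap", "p_stretch", "p_equalize", "p_invert", "p_rotate", "p_translate", "p_blur", "p_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.synthetic_fraction
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("synthetic_fraction bounds must be ordered within [0, 1]")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(p_crop=0, p_channel_swap=0, p_stretch=0, p_equalize=0, p_invert=0, p_rotate=0, p_translate=0, p_blur=0, p_noise=0)


def _transform_masks(s: InstanceSet, fn, out_shape: tuple[int, int]) -> InstanceSet:
    """Apply a geometric transform to each object mask (nearest-neighbor)."""
    objects, labels = [], []
    for i in range(len(s)):
        m = fn(s.object_mask(i))
        coords = np.argwhere(m)
        if coords.shape[0] >= MIN_OBJECT_PIXELS:
            objects.append(coords)
            labels.append(s.labels[i])
    return InstanceSet(out_shape[0], out_shape[1], objects, labels)


def augment_sample(
    image: np.ndarray,
    s: InstanceSet,
    cfg: AugmentConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, InstanceSet]:
    """Randomly augment one image/instance pair; deterministic given the seed.

    With all operator probabilities zero this is the identity.  Objects pushed
    (mostly) outside the canvas by cropping or translation are dropped once
    fewer than 4 pixels remain.
    """
    cfg = cfg or AugmentConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.asarray(image, dtype=np.float64).copy()
    inst = s

    # --- geometric ops (image and masks together) ---
    if rng.random() < cfg.p_crop:
        frac = rng.uniform(*cfg.crop_fraction)
        ch = max(8, int(round(s.height * frac)))
        cw = max(8, int(round(s.width * frac)))
        if ch > inst.height or cw > inst.width:
            raise ValueError("crop larger than the canvas")
        r0 = int(rng.integers(0, inst.height - ch + 1))
        c0 = int(rng.integers(0, inst.width - cw + 1))
        img = img[r0 : r0 + ch, c0 : c0 + cw]

        def crop_fn(m, r0=r0, c0=c0, ch=ch, cw=cw):
            return m[r0 : r0 + ch, c0 : c0 + cw]

        inst = _transform_masks(inst, crop_fn, (ch, cw))
    if rng.random() < cfg.p_rotate:
        angle = float(rng.uniform(*cfg.rotation_degrees))
        if img.ndim == 3:
            img = np.stack([rotate(img[:, :, c], angle, order=1, mode="reflect", preserve_range=True) for c in range(img.shape[2])], axis=2)
        else:
            img = rotate(img, angle, order=1, mode="reflect", preserve_range=True)
        inst = _transform_masks(
            inst,
            lambda m: rotate(m.astype(float), angle, order=0, mode="constant", cval=0, preserve_range=True) > 0.5,
            inst.shape,
        )
    if rng.random() < cfg.p_translate:
        dr = int(rng.integers(-int(inst.height * cfg.translate_fraction), int(inst.height * cfg.translate_fraction) + 1))
        dc = int(rng.integers(-int(inst.width * cfg.translate_fraction), int(inst.width * cfg.translate_fraction) + 1))

        def shift_arr(a, order):
            if a.ndim == 3:
                return np.stack([ndi.shift(a[:, :, c], (dr, dc), order=order, mode="constant", cval=0.0) for c in range(a.shape[2])], axis=2)
            return ndi.shift(a, (dr, dc), order=order, mode="constant", cval=0.0)

        img = shift_arr(img, order=1)
        inst = _transform_masks(inst, lambda m: shift_arr(m.astype(float), order=0) > 0.5, inst.shape)

    # --- photometric ops (image only) ---
    if img.ndim == 3 and rng.random() < cfg.p_channel_swap:
        img = img[:, :, rng.permutation(img.shape[2])]
    if rng.random() < cfg.p_stretch:
        lo, hi = np.percentile(img, cfg.stretch_percentiles)
        if hi > lo:
            img = exposure.rescale_intensity(img, in_range=(lo, hi), out_range=(0.0, 1.0))
    if rng.random() < cfg.p_equalize:
        img = exposure.equalize_hist(img)
    if rng.random() < cfg.p_invert:
        img = img.max() + img.min() - img
    if rng.random() < cfg.p_blur:
        sigma = float(rng.uniform(*cfg.blur_sigma))
        img = ndi.gaussian_filter(img, sigma=sigma if img.ndim == 2 else (sigma, sigma, 0))
    if rng.random() < cfg.p_noise:
        sd = float(rng.uniform(*cfg.noise_sd))
        img = img + rng.normal(0.0, sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), inst


def mix_batch(
    real: list,
    synthetic: list,
    fraction_range: tuple[float, float] = (0.10, 0.50),
    batch: int = 16,
    seed: int | np.random.Generator = 0,
) -> list:
    """Compose one minibatch with a bounded synthetic fraction.

    The synthetic count is ``round(batch * u)`` for ``u`` drawn uniformly in
    ``fraction_range``; items are sampled with replacement from each pool and
    shuffled.  The composition is logged.
    """
    lo, hi = fraction_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("fraction_range must be ordered within [0, 1]")
    if batch < 0:
        raise ValueError("batch must be non-negative")
    if batch == 0:
        return []
    if not synthetic and lo > 0:
        raise ValueError("synthetic pool empty but a nonzero synthetic fraction is required")
    if not real and hi < 1.0:
        raise ValueError("real pool empty but a nonzero real fraction is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(lo, hi)
    n_syn = int(round(batch * u))
    n_real = batch - n_syn
    items = [real[i] for i in rng.integers(0, len(real), size=n_real)] if n_real else []
    items += [synthetic[i] for i in rng.integers(0, len(synthetic), size=n_syn)] if n_syn else []
    rng.shuffle(items)
    logger.info("mix_batch: %d real + %d synthetic (u=%.3f)", n_real, n_syn, u)
    return items
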