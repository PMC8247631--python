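"""Core data types, label-mask / RLE I/O and the deterministic toy-image generator.

The universal currency of the package is the :class:`InstanceSet`: an ordered
collection of per-object binary masks on a shared image canvas.  Objects *may*
overlap (raw detector output can), which is why a flat label image is a lossy
view: flattening is defined as last-object-wins and is only exactly invertible
for non-overlapping sets.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)`` everywhere in the library.
* Run-length encoding alone is 1-based and column-major, matching the Kaggle
  Data Science Bowl submission dialect.
* Label images are written as 16-bit single-channel PNG/TIFF, background 0.
* Images handled by the library are float arrays in ``[0, 1]``; files are
  written as 8-bit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage as ndi


class FormatError(ValueError):
    """A file exists but does not parse in the requested format."""


class GenerationError(RuntimeError):
    """The toy generator could not place the requested objects."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class InstanceSet:
    """A set of per-object binary masks over one image canvas.

    Parameters
    ----------
    height, width:
        Canvas dimensions in pixels.
    objects:
        One ``(k, 2)`` int array of 0-based (row, col) pixel coordinates per
        object.  Every object must be non-empty and lie within the canvas.
    labels:
        Unique positive integer identifier per object.  Defaults to 1..n.
    """

    height: int
    width: int
    objects: list[np.ndarray] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.objects = [np.asarray(o, dtype=np.int64).reshape(-1, 2) for o in self.objects]
        if not self.labels:
            self.labels = list(range(1, len(self.objects) + 1))
        if len(self.labels) != len(self.objects):
            raise ValueError("labels and objects length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if any(lab <= 0 for lab in self.labels):
            raise ValueError("labels must be positive")
        for coords in self.objects:
            if coords.shape[0] == 0:
                raise ValueError("objects must be non-empty")
            if (
                coords[:, 0].min() < 0
                or coords[:, 1].min() < 0
                or coords[:, 0].max() >= self.height
                or coords[:, 1].max() >= self.width
            ):
                raise ValueError("object pixels outside the canvas")

    # -- basic accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.objects)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def areas(self) -> np.ndarray:
        return np.array([len(c) for c in self.objects], dtype=np.int64)

    def centroids(self) -> np.ndarray:
        """(n, 2) array of object centroids in (row, col)."""
        if not self.objects:
            return np.zeros((0, 2))
        return np.array([c.mean(axis=0) for c in self.objects])

    def object_mask(self, i: int) -> np.ndarray:
        """Full-canvas boolean mask of object ``i`` (by position, not label)."""
        m = np.zeros(self.shape, dtype=bool)
        c = self.objects[i]
        m[c[:, 0], c[:, 1]] = True
        return m

    def ravelled(self, i: int, order: str = "C") -> np.ndarray:
        """Sorted flat pixel indices of object ``i`` (for fast set algebra)."""
        c = self.objects[i]
        if order == "C":
            idx = c[:, 0] * self.width + c[:, 1]
        else:  # column-major, used by the Kaggle RLE dialect
            idx = c[:, 1] * self.height + c[:, 0]
        return np.sort(idx)

    # -- conversions --------------------------------------------------------

    def to_label_image(self) -> np.ndarray:
        """Flatten to a uint16 label image; overlaps resolved last-object-wins."""
        img = np.zeros(self.shape, dtype=np.uint16)
        for coords, lab in zip(self.objects, self.labels):
            img[coords[:, 0], coords[:, 1]] = lab
        return img

    @classmethod
    def from_label_image(cls, label_img: np.ndarray) -> "InstanceSet":
        label_img = np.asarray(label_img)
        if not np.issubdtype(label_img.dtype, np.integer):
            if np.issubdtype(label_img.dtype, np.floating) and np.allclose(
                label_img, np.round(label_img)
            ):
                label_img = np.round(label_img).astype(np.int64)
            else:
                raise FormatError("label image must have integer values")
        h, w = label_img.shape
        labs = np.unique(label_img)
        labs = labs[labs > 0]
        objects, labels = [], []
        for lab in labs:
            coords = np.argwhere(label_img == lab)
            objects.append(coords)
            labels.append(int(lab))
        return cls(h, w, objects, labels)

    @classmethod
    def from_masks(cls, masks: Iterable[np.ndarray], labels: Sequence[int] | None = None) -> "InstanceSet":
        """Build from full-canvas boolean masks (objects may overlap)."""
        masks = list(masks)
        if not masks:
            raise ValueError("from_masks needs at least one mask; use InstanceSet(h, w) for empty sets")
        h, w = masks[0].shape
        objects = [np.argwhere(np.asarray(m, dtype=bool)) for m in masks]
        return cls(h, w, objects, list(labels) if labels is not None else [])

    def relabeled(self) -> "InstanceSet":
        """Same objects with fresh consecutive labels 1..n."""
        return InstanceSet(self.height, self.width, [c.copy() for c in self.objects])


@dataclass
class ProbabilityMap:
    """Per-pixel foreground probability on the same canvas as an InstanceSet."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.clip(np.asarray(self.values, dtype=np.float64), 0.0, 1.0)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class RLEString:
    """Kaggle-dialect run-length encoding of one object: 1-based column-major."""

    label: int
    runs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.runs = sorted((int(s), int(l)) for s, l in self.runs)
        prev_end = 0
        for start, length in self.runs:
            if start <= prev_end:
                raise ValueError("RLE runs overlap or are unsorted")
            if length <= 0:
                raise ValueError("RLE run length must be positive")
            prev_end = start + length - 1

    def to_string(self) -> str:
        return " ".join(f"{s} {l}" for s, l in self.runs)

    @classmethod
    def from_string(cls, text: str, label: int = 1) -> "RLEString":
        tokens = text.split()
        if len(tokens) % 2:
            raise FormatError("RLE string must contain start/length pairs")
        nums = [int(t) for t in tokens]
        return cls(label, list(zip(nums[::2], nums[1::2])))


# ---------------------------------------------------------------------------
# RLE encode / decode
# ---------------------------------------------------------------------------


def rle_encode(mask: np.ndarray, label: int = 1) -> RLEString:
    """Encode a binary mask as Kaggle-dialect RLE (1-based, column-major)."""
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel(order="F")
    # transitions of the padded sequence give run starts/ends
    padded = np.concatenate([[False], flat, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1  # 1-based
    ends = np.flatnonzero(diff == -1) + 1
    runs = [(int(s), int(e - s)) for s, e in zip(starts, ends)]
    return RLEString(label, runs)


def rle_decode(rle: RLEString, shape: tuple[int, int]) -> np.ndarray:
    """Decode an RLEString to a full-canvas boolean mask."""
    h, w = shape
    flat = np.zeros(h * w, dtype=bool)
    for start, length in rle.runs:
        if start + length - 1 > h * w:
            raise FormatError("RLE run exceeds the canvas")
        flat[start - 1 : start - 1 + length] = True
    return flat.reshape((h, w), order="F")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _read_label_array(path: Path) -> np.ndarray:
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise OSError(f"cannot read image {path}") from exc
    if arr.ndim == 3:
        # single-channel images saved with a redundant channel axis
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise FormatError(f"{path}: label image must be single-channel")
    return arr


def read_instances(path: str | Path, format: str = "label-image", shape: tuple[int, int] | None = None) -> InstanceSet:
    """Read an InstanceSet from a label image or an RLE CSV.

    For ``format='rle'`` the CSV must have columns (ImageId, EncodedPixels)
    and ``shape`` gives the canvas; all rows are treated as one image.
    """
    path = Path(path)
    if format in ("label-image", "label"):
        arr = _read_label_array(path)
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError(f"{path}: non-integer label image")
        return InstanceSet.from_label_image(arr)
    if format in ("rle", "rle+shape"):
        if shape is None:
            raise ValueError("RLE format requires an explicit canvas shape")
        objects, labels = [], []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "EncodedPixels" not in reader.fieldnames:
                raise FormatError(f"{path}: expected columns ImageId, EncodedPixels")
            for i, row in enumerate(reader, start=1):
                enc = (row["EncodedPixels"] or "").strip()
                if not enc:
                    continue
                mask = rle_decode(RLEString.from_string(enc, label=i), shape)
                objects.append(np.argwhere(mask))
                labels.append(i)
        return InstanceSet(shape[0], shape[1], objects, labels)
    raise ValueError(f"unknown format {format!r}")


def write_instances(s: InstanceSet, path: str | Path, format: str = "label-image", image_id: str = "image") -> None:
    """Write an InstanceSet as a 16-bit label image or a Kaggle-dialect RLE CSV.

    Label images flatten overlaps last-object-wins; RLE preserves each object.
    """
    path = Path(path)
    if s.height <= 0 or s.width <= 0:
        raise ValueError("degenerate canvas")
    if format in ("label-image", "label"):
        img = s.to_label_image()
        if path.suffix.lower() in {".tif", ".tiff"}:
            tifffile.imwrite(path, img)
        else:
            iio.imwrite(path, img)
    elif format in ("rle", "rle+shape"):
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["ImageId", "EncodedPixels"])
            for i in range(len(s)):
                rle = rle_encode(s.object_mask(i), label=s.labels[i])
                writer.writerow([image_id, rle.to_string()])
    else:
        raise ValueError(f"unknown format {format!r}")


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a float image in [0, 1] (or uint8) as an 8-bit file."""
    image = np.asarray(image)
    if image.dtype != np.uint8:
        image = (np.clip(image, 0.0, 1.0) * 255).round().astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def read_image(path: str | Path) -> np.ndarray:
    """Read an image file as float in [0, 1] (grayscale or RGB preserved)."""
    path = Path(path)
    arr = tifffile.imread(path) if path.suffix.lower() in {".tif", ".tiff"} else iio.imread(path)
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Toy fixture generator
# ---------------------------------------------------------------------------


def _ellipse_coords(center: tuple[float, float], d: float, ecc: float, angle: float, shape: tuple[int, int]) -> np.ndarray:
    """Pixel coordinates of a rotated ellipse of equivalent diameter ``d``."""
    a = (d / 2.0) / (1.0 - ecc**2) ** 0.25
    b = (d / 2.0) * (1.0 - ecc**2) ** 0.25
    cy, cx = center
    h, w = shape
    r0 = max(int(np.floor(cy - a - 2)), 0)
    r1 = min(int(np.ceil(cy + a + 2)), h - 1)
    c0 = max(int(np.floor(cx - a - 2)), 0)
    c1 = min(int(np.ceil(cx + a + 2)), w - 1)
    yy, xx = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(angle) + dx * np.sin(angle)
    v = -dy * np.sin(angle) + dx * np.cos(angle)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return np.stack([yy[inside], xx[inside]], axis=1)


def make_toy_dataset(
    n_images: int,
    objects_per_image: tuple[int, int] = (5, 10),
    diameter: tuple[float, float] = (14.0, 20.0),
    seed: int = 0,
    canvas: tuple[int, int] = (128, 128),
    fg_intensity: float = 0.8,
    bg_intensity: float = 0.15,
    noise_sd: float = 0.03,
    max_retries: int = 1000,
) -> list[tuple[np.ndarray, InstanceSet]]:
    """Generate labeled toy microscopy images with exact ground truth.

    Objects are non-overlapping rasterized ellipses of controlled equivalent
    diameter; the image is a smoothed foreground/background intensity field
    plus Gaussian noise.  Fully deterministic given ``seed``.
    """
    if n_images < 0 or objects_per_image[0] < 0 or diameter[0] <= 0:
        raise ValueError("ranges must be positive")
    rng = np.random.default_rng(seed)
    h, w = canvas
    out: list[tuple[np.ndarray, InstanceSet]] = []
    for _ in range(n_images):
        n_obj = int(rng.integers(objects_per_image[0], objects_per_image[1] + 1))
        occupied = np.zeros((h, w), dtype=bool)
        objects: list[np.ndarray] = []
        for _ in range(n_obj):
            placed = False
            for _ in range(max_retries):
                d = rng.uniform(diameter[0], diameter[1])
                ecc = rng.uniform(0.0, 0.5)
                ang = rng.uniform(0.0, np.pi)
                margin = d / 2 + 2
                if h - margin <= margin or w - margin <= margin:
                    raise GenerationError("canvas too small for requested diameter")
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, w - margin)
                coords = _ellipse_coords((cy, cx), d, ecc, ang, (h, w))
                if coords.shape[0] == 0:
                    continue
                # 1-px clearance so distinct objects never touch
                patch = np.zeros((h, w), dtype=bool)
                patch[coords[:, 0], coords[:, 1]] = True
                grown = ndi.binary_dilation(patch, iterations=1)
                if not (grown & occupied).any():
                    occupied |= patch
                    objects.append(coords)
                    placed = True
                    break
            if not placed:
                raise GenerationError(
                    f"could not place {n_obj} objects of diameter {diameter} on {canvas}"
                )
        instances = InstanceSet(h, w, objects)
        img = np.full((h, w), bg_intensity, dtype=np.float64)
        img[occupied] = fg_intensity
        img = ndi.gaussian_filter(img, sigma=1.0)
        img = img + rng.normal(0.0, noise_sd, size=(h, w))
        out.append((np.clip(img, 0.0, 1.0), instances))
    return out
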