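"""Group unannotated images into appearance ("style") clusters.

Each image is summarized by a fixed feature vector (intensity statistics,
gray-level co-occurrence texture, edge density, foreground fraction).  A
pairwise similarity is computed between images — by a small trained network on
labeled same-condition / different-condition pairs when such labels exist,
otherwise by a Gaussian kernel on standardized feature distance — and the
rows of the resulting similarity matrix are clustered with k-means.  The
number of clusters deliberately over-segments (about one cluster per 15
images) so that dissimilar imaging conditions are never forced together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import graycomatrix
from skimage.filters import sobel, threshold_otsu
from sklearn.cluster import KMeans
from sklearn.neural_network import MLPClassifier

IMAGES_PER_CLUSTER = 15
GLCM_LEVELS = 32

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"ch{c}_{s}" for c in range(3) for s in ("mean", "sd", "p01", "p50", "p99")]
    + ["glcm_contrast", "glcm_correlation", "glcm_homogeneity", "glcm_entropy"]
    + ["edge_density", "foreground_fraction"]
)


@dataclass
class SimilarityModel:
    """Symmetric pairwise similarity from feature-pair differences.

    ``kind='learned'`` wraps a shallow fully connected classifier applied to
    |a - b| (symmetric by construction), trained on same/different-condition
    pairs.  ``kind='metric-fallback'`` is a Gaussian kernel
    ``exp(-d^2 / scale^2)`` on standardized Euclidean distance, used when no
    labeled pairs are available.
    """

    kind: str
    mean: np.ndarray
    sd: np.ndarray
    estimator: MLPClassifier | None = None
    scale: float = 1.0

    def _z(self, v: np.ndarray) -> np.ndarray:
        return (np.asarray(v, dtype=np.float64) - self.mean) / self.sd

    def similarity(self, a: np.ndarray, b: np.ndarray) -> float:
        za, zb = self._z(a), self._z(b)
        if self.kind == "learned":
            assert self.estimator is not None
            return float(self.estimator.predict_proba(np.abs(za - zb)[None, :])[0, 1])
        d2 = float(np.sum((za - zb) ** 2))
        return float(np.exp(-d2 / self.scale**2))

    def matrix(self, features: Sequence[np.ndarray]) -> np.ndarray:
        n = len(features)
        s = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                s[i, j] = s[j, i] = self.similarity(features[i], features[j])
        np.fill_diagonal(s, 1.0)
        return s


@dataclass
class StyleClustering:
    k: int
    assignment: np.ndarray  # image index -> cluster id
    similarity: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster)


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def _trim_constant_border(img: np.ndarray) -> np.ndarray:
    """Strip any constant border so features ignore uniform padding."""
    g = img if img.ndim == 2 else img.mean(axis=2)
    corner = g[0, 0]
    rows = np.flatnonzero(~np.all(np.isclose(g, corner), axis=1))
    cols = np.flatnonzero(~np.all(np.isclose(g, corner), axis=0))
    if rows.size == 0 or cols.size == 0:
        return img  # fully constant image
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    if (r1 - r0) < 16 or (c1 - c0) < 16:
        return img
    return img[r0:r1, c0:c1]


def _glcm_stats(gray: np.ndarray) -> tuple[float, float, float, float]:
    """Offset-averaged co-occurrence contrast/correlation/homogeneity/entropy.

    Two offsets (1 px right, 1 px down) are averaged, making the statistics
    invariant to 90-degree rotations.  A constant image yields all zeros
    (correlation is defined as 0 when the marginal variance vanishes).
    """
    q = np.clip((gray * (GLCM_LEVELS - 1)).round().astype(np.uint8), 0, GLCM_LEVELS - 1)
    glcm = graycomatrix(q, distances=[1], angles=[0, np.pi / 2], levels=GLCM_LEVELS, symmetric=True, normed=True)
    contrasts, correlations, homogeneities, entropies = [], [], [], []
    levels = np.arange(GLCM_LEVELS, dtype=np.float64)
    ii, jj = np.meshgrid(levels, levels, indexing="ij")
    for a in range(glcm.shape[3]):
        p = glcm[:, :, 0, a]
        contrasts.append(np.sum(p * (ii - jj) ** 2))
        mu_i = np.sum(p * ii)
        mu_j = np.sum(p * jj)
        var_i = np.sum(p * (ii - mu_i) ** 2)
        var_j = np.sum(p * (jj - mu_j) ** 2)
        if var_i > 1e-12 and var_j > 1e-12:
            correlations.append(np.sum(p * (ii - mu_i) * (jj - mu_j)) / np.sqrt(var_i * var_j))
        else:
            correlations.append(0.0)
        homogeneities.append(np.sum(p / (1.0 + (ii - jj) ** 2)))
        nz = p[p > 0]
        entropies.append(-np.sum(nz * np.log2(nz)) if nz.size else 0.0)
    return (
        float(np.mean(contrasts)),
        float(np.mean(correlations)),
        float(np.mean(homogeneities)),
        float(np.mean(entropies)),
    )


def extract_features(image: np.ndarray) -> np.ndarray:
    """Fixed-length appearance descriptor of one image.

    Per channel (grayscale replicated to 3): mean, sd, 1st/50th/99th
    percentiles; offset-averaged co-occurrence texture; edge density (mean
    Sobel magnitude); Otsu foreground fraction.  Deterministic, finite, and
    insensitive to constant borders (trimmed before measurement).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim not in (2, 3):
        raise ValueError("expected a 2D grayscale or 3-channel image")
    if min(image.shape[:2]) < 16:
        raise ValueError("image must be at least 16x16")
    image = _trim_constant_border(image)
    if image.ndim == 2:
        channels = [image, image, image]
        gray = image
    else:
        channels = [image[:, :, c] for c in range(3)]
        gray = rgb2gray(image[:, :, :3])
    feats: list[float] = []
    for ch in channels:
        feats += [
            float(ch.mean()),
            float(ch.std()),
            float(np.percentile(ch, 1)),
            float(np.percentile(ch, 50)),
            float(np.percentile(ch, 99)),
        ]
    gray = np.clip(gray, 0.0, 1.0)
    feats += list(_glcm_stats(gray))
    feats.append(float(np.abs(sobel(gray)).mean()))
    if gray.max() - gray.min() < 1e-12:
        feats.append(0.0)
    else:
        feats.append(float((gray > threshold_otsu(gray)).mean()))
    vec = np.array(feats, dtype=np.float64)
    assert vec.shape == (len(FEATURE_NAMES),) and np.all(np.isfinite(vec))
    return vec


# ---------------------------------------------------------------------------
# Similarity learning
# ---------------------------------------------------------------------------


def _standardizer(features: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(features, dtype=np.float64)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return mean, sd


def train_similarity(
    pairs: list[tuple[np.ndarray, np.ndarray, int]], seed: int = 0
) -> SimilarityModel:
    """Train the shallow same-condition classifier on labeled feature pairs.

    Pairs of images from the same imaging condition carry label 1, pairs from
    different conditions label 0.  The classifier sees |a - b| of z-scored
    features, so the learned similarity is symmetric by construction.
    """
    if len(pairs) < 10:
        raise ValueError("need at least 10 labeled pairs")
    labels = np.array([int(l) for _, _, l in pairs])
    if len(np.unique(labels)) < 2:
        raise ValueError("both pair labels (same=1 / different=0) must be present")
    all_feats = [a for a, _, _ in pairs] + [b for _, b, _ in pairs]
    mean, sd = _standardizer(all_feats)
    x = np.array([np.abs((a - mean) / sd - (b - mean) / sd) for a, b, _ in pairs])
    clf = MLPClassifier(
        hidden_layer_sizes=(16,),
        solver="lbfgs",
        alpha=1e-3,
        max_iter=2000,
        random_state=int(seed) % (2**31),
    )
    clf.fit(x, labels)
    return SimilarityModel(kind="learned", mean=mean, sd=sd, estimator=clf)


def metric_fallback_similarity(features: Sequence[np.ndarray]) -> SimilarityModel:
    """Unsupervised similarity: Gaussian kernel scaled by the median distance."""
    mean, sd = _standardizer(features)
    z = (np.asarray(features) - mean) / sd
    n = len(features)
    if n >= 2:
        d = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2))
        off = d[np.triu_indices(n, k=1)]
        scale = float(np.median(off[off > 0])) if np.any(off > 0) else 1.0
    else:
        scale = 1.0
    return SimilarityModel(kind="metric-fallback", mean=mean, sd=sd, scale=max(scale, 1e-12))


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def choose_k(n_images: int, oversegmentation: int = IMAGES_PER_CLUSTER) -> int:
    """Automatic cluster count: about one cluster per ``oversegmentation`` images.

    Over-segmenting keeps accidental mixing of truly different conditions rare;
    k is capped at the number of images and never below 1.
    """
    if n_images < 1:
        raise ValueError("need at least one image")
    return min(n_images, max(1, round(n_images / oversegmentation)))


def cluster_styles(
    features: Sequence[np.ndarray],
    model: SimilarityModel,
    k: int,
    seed: int = 0,
) -> StyleClustering:
    """k-means over similarity-matrix rows; deterministic given the seed."""
    n = len(features)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of images n={n}")
    sim = model.matrix(features)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
    assignment = km.fit_predict(sim)
    return StyleClustering(k=k, assignment=assignment, similarity=sim)


def filter_small_clusters(clustering: StyleClustering, min_size: int = 2) -> list[int]:
    """Cluster ids with at least ``min_size`` members.

    Styles backed by too few images give unreliable statistics and are
    excluded from synthesis; the threshold is a configurable convention.
    """
    return [c for c in range(clustering.k) if clustering.members(c).size >= min_size]
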