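import numpy as np
import pytest

from nucseg import InstanceSet, make_toy_dataset


@pytest.fixture(scope="session")
def toy_data():
    """Ten toy images with exact ground truth, ~17 px nuclei."""
    return make_toy_dataset(10, objects_per_image=(5, 8), diameter=(14, 20), seed=11)


@pytest.fixture(scope="session")
def two_style_data():
    """Two visually distinct fixture styles: bright-on-dark and dark-on-bright."""
    bright = make_toy_dataset(20, (5, 8), (14, 20), seed=21, fg_intensity=0.85, bg_intensity=0.15)
    dark = make_toy_dataset(20, (5, 8), (14, 20), seed=22, fg_intensity=0.2, bg_intensity=0.75)
    return bright, dark


def random_instances(rng: np.random.Generator, shape=(32, 32), max_objects=5) -> InstanceSet:
    """Random rectangles (possibly overlapping) as an InstanceSet."""
    h, w = shape
    n = int(rng.integers(0, max_objects + 1))
    objects = []
    for _ in range(n):
        rh = int(rng.integers(3, 10))
        rw = int(rng.integers(3, 10))
        r0 = int(rng.integers(0, h - rh))
        c0 = int(rng.integers(0, w - rw))
        yy, xx = np.mgrid[r0 : r0 + rh, c0 : c0 + rw]
        objects.append(np.stack([yy.ravel(), xx.ravel()], axis=1))
    return InstanceSet(h, w, objects)
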