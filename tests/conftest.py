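import dataclasses

import numpy as np
import pytest

from dermopt import synthetic


@pytest.fixture
def clean_disk_spec():
    """Noise-free perfect disk on a uniform background."""
    return synthetic.LesionSpec(
        image_height=48, image_width=48, noise_sd=0.0,
        boundary_irregularity=0.0, lesion_radius_range=(8.0, 14.0), seed=0)


@pytest.fixture
def disk_pairs(clean_disk_spec):
    """Six noise-free disk images with ground-truth masks."""
    pairs = []
    for s in range(6):
        img, mask = synthetic.generate_lesion_image(
            dataclasses.replace(clean_disk_spec, seed=s))
        pairs.append((img, mask))
    return pairs


@pytest.fixture
def noisy_lesion():
    """One realistic irregular noisy lesion (image, mask)."""
    spec = synthetic.LesionSpec(boundary_irregularity=0.4, noise_sd=8.0, seed=3)
    return synthetic.generate_lesion_image(spec)


def rasterize_disk(h, w, cy, cx, r):
    """Brute-force point-in-circle rasterization oracle."""
    mask = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            if (i - cy) ** 2 + (j - cx) ** 2 <= r**2:
                mask[i, j] = True
    return mask
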