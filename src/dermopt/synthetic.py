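"""Seeded synthetic dermoscopy-like data.

Real dermoscopy corpora are large external downloads; every stage of the
pipeline is instead exercised on synthetic images that reproduce the two
properties the method actually relies on: melanoma-like lesions are *darker*
than the surrounding skin and have *irregular* boundaries, while benign
lesions are rounder and lighter.  The generator draws a lesion as a radially
perturbed disk

    r(theta) = r0 * (1 + irregularity * s(theta)),   max|s| <= 1,

where ``s`` is a smooth random trigonometric polynomial, composites it onto a
uniform skin background and adds clipped Gaussian noise.  Labeled feature
tables with a controlled informative/noise split are generated for the
selection and classification stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LesionSpec:
    """Parameters of one synthetic dermoscopy image.

    Intensities are 8-bit gray levels; geometry is in pixels.
    ``boundary_irregularity`` is the dimensionless radial perturbation
    amplitude (0 = perfect disk).
    """

    image_height: int = 64
    image_width: int = 64
    lesion_count: int = 1
    lesion_radius_range: tuple[float, float] = (10.0, 16.0)
    boundary_irregularity: float = 0.3
    lesion_intensity: float = 70.0
    skin_intensity: float = 180.0
    noise_sd: float = 8.0
    seed: int = 0


@dataclass(frozen=True)
class FeatureTableSpec:
    """Parameters of a labeled two-class feature table."""

    n_samples: int = 50            # per class
    n_features: int = 19
    informative_indices: tuple[int, ...] = (0, 1, 2)
    class_separation: float = 3.0  # mean shift on informative features
    noise_sd: float = 1.0
    seed: int = 0


def _validate_lesion_spec(spec: LesionSpec) -> None:
    if spec.image_height <= 0 or spec.image_width <= 0:
        raise ValueError("image dimensions must be positive")
    if spec.lesion_count < 0:
        raise ValueError("lesion_count must be >= 0")
    rlo, rhi = spec.lesion_radius_range
    if rlo <= 0 or rhi < rlo:
        raise ValueError("invalid lesion_radius_range")
    max_extent = rhi * (1.0 + spec.boundary_irregularity)
    if 2 * max_extent > min(spec.image_height, spec.image_width):
        raise ValueError("lesion radius exceeds image bounds")
    for v in (spec.lesion_intensity, spec.skin_intensity):
        if not (0.0 <= v <= 255.0):
            raise ValueError("intensities must lie in [0, 255]")
    if spec.boundary_irregularity < 0 or spec.noise_sd < 0:
        raise ValueError("irregularity and noise_sd must be >= 0")


def _boundary_profile(rng: np.random.Generator, n_harmonics: int = 4):
    """Random smooth periodic perturbation s(theta) with max|s| = 1."""
    amps = rng.uniform(0.3, 1.0, size=n_harmonics)
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
    ks = np.arange(2, 2 + n_harmonics)

    theta_grid = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    raw = np.sum(amps[:, None] * np.sin(ks[:, None] * theta_grid + phases[:, None]), axis=0)
    scale = np.max(np.abs(raw))

    def s(theta: np.ndarray) -> np.ndarray:
        val = np.sum(
            amps[:, None] * np.sin(ks[:, None] * theta.ravel()[None, :] + phases[:, None]),
            axis=0,
        )
        return (val / scale).reshape(theta.shape)

    return s


def generate_lesion_image(spec: LesionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one grayscale image and its exact ground-truth mask.

    Returns ``(image, mask)`` — image is float64 in [0, 255] (uint8-valued
    when ``noise_sd == 0``), mask is uint8 in {0, 1} with 1 = lesion.
    Deterministic given ``spec.seed``.
    """
    _validate_lesion_spec(spec)
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    mask = np.zeros((h, w), dtype=bool)
    rows, cols = np.mgrid[0:h, 0:w]

    rlo, rhi = spec.lesion_radius_range
    for _ in range(spec.lesion_count):
        r0 = rng.uniform(rlo, rhi)
        margin = r0 * (1.0 + spec.boundary_irregularity) + 1.0
        cy = rng.uniform(margin, h - margin) if h > 2 * margin else h / 2.0
        cx = rng.uniform(margin, w - margin) if w > 2 * margin else w / 2.0
        dy, dx = rows - cy, cols - cx
        dist = np.hypot(dy, dx)
        if spec.boundary_irregularity > 0:
            s = _boundary_profile(rng)
            theta = np.arctan2(dy, dx)
            radius = r0 * (1.0 + spec.boundary_irregularity * s(theta))
        else:
            radius = r0
        mask |= dist <= radius

    img = np.where(mask, spec.lesion_intensity, spec.skin_intensity).astype(float)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 255.0)
    return img, mask.astype(np.uint8)


def generate_feature_table(spec: FeatureTableSpec) -> pd.DataFrame:
    """Labeled feature table with class labels in {+1, -1}.

    Only features listed in ``informative_indices`` have class-dependent
    means (population gap of exactly ``class_separation``); all others are
    N(0, noise_sd) in both classes.
    """
    if spec.n_samples <= 0:
        raise ValueError("n_samples must be positive (no empty classes)")
    if spec.informative_indices and spec.n_features < max(spec.informative_indices) + 1:
        raise ValueError("informative index outside feature range")
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    X = rng.normal(0.0, spec.noise_sd, size=(2 * n, p))
    y = np.concatenate([np.ones(n, dtype=int), -np.ones(n, dtype=int)])
    half = spec.class_separation / 2.0
    for j in spec.informative_indices:
        X[:n, j] += half
        X[n:, j] -= half
    cols = [f"f{j:02d}" for j in range(p)]
    df = pd.DataFrame(X, columns=cols)
    df["label"] = y
    return df


# -- labeled image datasets (benign vs malignant lesion classes) -------------

#: Default class geometries: benign lesions are round and lighter, malignant
#: lesions are irregular and darker — the contrast the geometric and
#: statistical features are designed to pick up.
BENIGN_SPEC = LesionSpec(boundary_irregularity=0.05, lesion_intensity=110.0,
                         lesion_radius_range=(9.0, 14.0), noise_sd=6.0)
MALIGNANT_SPEC = LesionSpec(boundary_irregularity=0.55, lesion_intensity=60.0,
                            lesion_radius_range=(10.0, 16.0), noise_sd=6.0)


def generate_labeled_images(
    n_per_class: int,
    seed: int = 0,
    benign: LesionSpec = BENIGN_SPEC,
    malignant: LesionSpec = MALIGNANT_SPEC,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Two-class image set: label +1 = malignant, -1 = benign.

    Returns (images, masks, labels); per-sample seeds are derived from
    ``seed`` so the whole dataset is reproducible.
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    rng = np.random.default_rng(seed)
    images, masks, labels = [], [], []
    for label, base in ((1, malignant), (-1, benign)):
        for _ in range(n_per_class):
            sub = dataclasses.replace(base, seed=int(rng.integers(2**31)))
            img, mask = generate_lesion_image(sub)
            images.append(img)
            masks.append(mask)
            labels.append(label)
    return images, masks, np.asarray(labels)


# -- PNG / CSV plumbing ------------------------------------------------------

def write_image_png(path, img: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.clip(np.round(img), 0, 255).astype(np.uint8))


def write_mask_png(path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))


def read_image(path) -> np.ndarray:
    """Read a grayscale image (PNG/JPEG); RGB inputs are luma-converted."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    return arr.astype(float)


def read_mask(path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)
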