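"""Lesion feature extraction: geometry, GLCM texture, intensity statistics
and Hu invariant moments.

The 19 values produced per (image, mask) pair, in their fixed output order:

geometric (from the binary mask; largest connected component)
    rectangularity   A / (a·b)
    elongation       b / a
    area             foreground pixel count A
    form_factor      A / a²
    solidity         A / convex-hull area
    irregularity_index  4πA / P²  (1 for a circle, smaller when irregular)
    perimeter        boundary-length estimate P
    eccentricity     √(a² − b²) / a
texture (from a masked gray-level co-occurrence matrix)
    contrast, energy, homogeneity, correlation
statistical (over masked pixel intensities)
    mean, entropy (bits), variance, std
shape invariants
    hu1, hu2, hu3    φ1 = η20+η02, φ2 = (η20−η02)²+4η11², φ3 = (η30−3η12)²+(3η21−η03)²

``a`` and ``b`` are the pixel-coordinate extents along the major/minor
principal (second-moment) axes of the component, so an axis-aligned h×w
rectangle has a = max(h, w), b = min(h, w) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

FEATURE_NAMES = (
    "rectangularity", "elongation", "area", "form_factor", "solidity",
    "irregularity_index", "perimeter", "eccentricity",
    "contrast", "energy", "homogeneity", "correlation",
    "mean", "entropy", "variance", "std",
    "hu1", "hu2", "hu3",
)


@dataclass
class FeatureConfig:
    glcm_levels: int = 8
    glcm_offset: tuple[int, int] = (0, 1)
    #: use the printed (dimensionally inconsistent) elongation/eccentricity
    #: forms 2A/(aπ) and 2a(a² − b²) instead of the standard ones
    legacy_formulas: bool = False


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected foreground component of a {0,1} mask."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def principal_extents(mask: np.ndarray) -> tuple[float, float]:
    """Major/minor axis lengths as extents along the principal axes.

    Pixel centers are projected onto the eigenvectors of the coordinate
    covariance matrix; each axis length is (max − min + 1) of the
    projections, counting the unit pixel footprint.
    """
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([ys, xs]).astype(float)
    pts -= pts.mean(axis=0)
    if len(pts) == 1:
        return 1.0, 1.0
    cov = np.cov(pts.T)
    _, vecs = np.linalg.eigh(cov)   # ascending eigenvalues
    proj = pts @ vecs
    minor = float(proj[:, 0].max() - proj[:, 0].min() + 1.0)
    major = float(proj[:, 1].max() - proj[:, 1].min() + 1.0)
    if minor > major:
        major, minor = minor, major
    return major, minor


def geometric_features(mask: np.ndarray, config: FeatureConfig | None = None) -> dict:
    """Eight shape descriptors of the largest lesion component."""
    config = config or FeatureConfig()
    comp = largest_component(mask)
    area = float(comp.sum())
    a, b = principal_extents(comp)
    perimeter = float(measure.perimeter(comp, neighborhood=4))
    convex_area = float(measure.regionprops(comp.astype(np.uint8))[0].area_convex)
    if config.legacy_formulas:
        elongation = 2.0 * area / (a * np.pi)
        eccentricity = 2.0 * a * (a**2 - b**2)
    else:
        elongation = b / a
        eccentricity = float(np.sqrt(max(a**2 - b**2, 0.0)) / a)
    return {
        "rectangularity": area / (a * b),
        "elongation": elongation,
        "area": area,
        "form_factor": area / a**2,
        "solidity": area / convex_area,
        "irregularity_index": 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0,
        "perimeter": perimeter,
        "eccentricity": eccentricity,
    }


# -- GLCM --------------------------------------------------------------------

@dataclass
class GLCM:
    """Symmetric normalized co-occurrence matrix restricted to a mask."""

    p: np.ndarray                  # (levels, levels), sums to 1
    levels: int
    offset: tuple[int, int]

    @property
    def marginals(self):
        i = np.arange(self.levels)
        pr = self.p.sum(axis=1)
        pc = self.p.sum(axis=0)
        mu_r = float(np.sum(i * pr))
        mu_c = float(np.sum(i * pc))
        sd_r = float(np.sqrt(np.sum((i - mu_r) ** 2 * pr)))
        sd_c = float(np.sqrt(np.sum((i - mu_c) ** 2 * pc)))
        return mu_r, mu_c, sd_r, sd_c


def quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Quantize [0, 255] intensities to integer levels 0..levels−1."""
    q = np.floor(np.asarray(img, dtype=float) / 256.0 * levels).astype(int)
    return np.clip(q, 0, levels - 1)


def build_glcm(img: np.ndarray, mask: np.ndarray, levels: int = 8,
               offset: tuple[int, int] = (0, 1)) -> GLCM:
    """Co-occurrence counts of quantized levels among in-mask pixel pairs.

    skimage's graycomatrix cannot restrict pairs to a mask, so the count is
    done directly: a pair contributes when both endpoints lie in the mask.
    The matrix is symmetrized and normalized to sum 1.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    mask = np.asarray(mask).astype(bool)
    q = quantize(img, levels)
    dr, dc = offset
    h, w = q.shape
    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    valid = mask[r0, c0] & mask[r1, c1]
    if valid.sum() < 2:
        raise ValueError("mask contains fewer than 2 eligible pixel pairs")
    pairs_i = q[r0, c0][valid]
    pairs_j = q[r1, c1][valid]
    counts = np.zeros((levels, levels), dtype=float)
    np.add.at(counts, (pairs_i, pairs_j), 1.0)
    counts = counts + counts.T
    return GLCM(counts / counts.sum(), levels, (dr, dc))


def texture_features(g: GLCM) -> dict:
    """Contrast, energy, homogeneity and correlation of a GLCM.

    Correlation is undefined (NaN) for constant regions (σr·σc = 0).
    """
    i, j = np.indices(g.p.shape)
    mu_r, mu_c, sd_r, sd_c = g.marginals
    if sd_r * sd_c > 0:
        corr = float(np.sum((i - mu_r) * (j - mu_c) * g.p) / (sd_r * sd_c))
    else:
        corr = float("nan")
    return {
        "contrast": float(np.sum((i - j) ** 2 * g.p)),
        "energy": float(np.sum(g.p**2)),
        "homogeneity": float(np.sum(g.p / (1.0 + np.abs(i - j)))),
        "correlation": corr,
    }


def statistical_features(img: np.ndarray, mask: np.ndarray) -> dict:
    """Mean/entropy/variance/std over masked pixel intensities.

    Entropy is log base 2 over the normalized histogram of the rounded
    intensities; 0·log 0 := 0.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(img, dtype=float)[mask]
    hist = np.bincount(np.clip(np.round(vals).astype(int), 0, 255), minlength=256)
    p = hist[hist > 0] / hist.sum()
    var = float(np.var(vals))
    return {
        "mean": float(np.mean(vals)),
        "entropy": float(-np.sum(p * np.log2(p))),
        "variance": var,
        "std": float(np.sqrt(var)),
    }


def hu_moments(mask: np.ndarray) -> tuple[float, float, float]:
    """First three Hu invariants of the binary shape.

    φ1 = η20 + η02;  φ2 = (η20 − η02)² + 4η11²;
    φ3 = (η30 − 3η12)² + (3η21 − η03)².
    """
    mask = np.asarray(mask).astype(float)
    if not mask.any():
        raise ValueError("empty mask")
    mu = measure.moments_central(mask, order=3)
    eta = measure.moments_normalized(mu, order=3)
    phi1 = eta[2, 0] + eta[0, 2]
    phi2 = (eta[2, 0] - eta[0, 2]) ** 2 + 4.0 * eta[1, 1] ** 2
    phi3 = (eta[3, 0] - 3.0 * eta[1, 2]) ** 2 + (3.0 * eta[2, 1] - eta[0, 3]) ** 2
    return float(phi1), float(phi2), float(phi3)


def extract_features(img: np.ndarray, mask: np.ndarray,
                     config: FeatureConfig | None = None) -> dict:
    """Assemble all 19 named feature values in FEATURE_NAMES order."""
    config = config or FeatureConfig()
    comp = largest_component(mask)
    out = geometric_features(comp, config)
    g = build_glcm(img, comp, levels=config.glcm_levels, offset=config.glcm_offset)
    out.update(texture_features(g))
    out.update(statistical_features(img, comp))
    out["hu1"], out["hu2"], out["hu3"] = hu_moments(comp)
    return {name: out[name] for name in FEATURE_NAMES}


def features_table(images, masks, labels=None,
                   config: FeatureConfig | None = None) -> pd.DataFrame:
    """One feature row per (image, mask) pair; optional final label column."""
    rows = [extract_features(im, mk, config) for im, mk in zip(images, masks)]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if labels is not None:
        df["label"] = np.asarray(labels)
    return df
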