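"""Fixed local-statistics features for the desk-scale models.

The synthetic textures differ only in locally computable statistics (mean
stain color, nucleus-blob density and scale, orientation coherence, noise
level), so the trainable models in this package operate on a small fixed
feature bank rather than learned convolutions: patch-level models see one
summary vector per patch, the segmenter sees the same statistics computed
per pixel over sliding windows.  The bank is deterministic and has no
trainable state, which keeps training CPU-cheap and bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, sobel, uniform_filter

from .synthcohort import LUMINANCE_WEIGHTS

#: grayscale level below which a pixel counts as "dark" (nucleus proxy)
DARK_LEVEL = 128.0

PATCH_FEATURE_NAMES = (
    "mean_lum",
    "std_lum",
    "dark_fraction",
    "dark_patchiness",
    "edge_energy",
    "coherence",
    "red_green",
    "green_blue",
    "lum_range",
)


def _luminance(pixels: np.ndarray) -> np.ndarray:
    return np.asarray(pixels, dtype=float) @ LUMINANCE_WEIGHTS


def _structure_tensor_coherence(gray: np.ndarray, sigma: float) -> np.ndarray:
    """Orientation coherence in [0, 1] from the smoothed structure tensor."""
    gr = sobel(gray, axis=0)
    gc = sobel(gray, axis=1)
    j11 = gaussian_filter(gr * gr, sigma)
    j22 = gaussian_filter(gc * gc, sigma)
    j12 = gaussian_filter(gr * gc, sigma)
    tr = j11 + j22
    det = j11 * j22 - j12 * j12
    disc = np.sqrt(np.maximum((j11 - j22) ** 2 + 4 * j12 * j12, 0.0))
    lam1 = 0.5 * (tr + disc)
    lam2 = 0.5 * (tr - disc)
    return np.where(tr > 1e-6, (lam1 - lam2) / (tr + 1e-6), 0.0)


def patch_features(pixels: np.ndarray) -> np.ndarray:
    """Summary feature vector for one RGB patch (see PATCH_FEATURE_NAMES)."""
    px = np.asarray(pixels, dtype=float)
    gray = _luminance(px)
    dark = gray < DARK_LEVEL
    # variance of coarse local dark fraction separates few-large-blob
    # textures from many-small-blob textures at equal dark fraction
    local_dark = uniform_filter(dark.astype(float), size=7)
    coher = _structure_tensor_coherence(gray, sigma=2.0)
    q10, q90 = np.percentile(gray, [10, 90])
    return np.array(
        [
            gray.mean() / 255.0,
            gray.std() / 255.0,
            dark.mean(),
            local_dark.std(),
            min(np.abs(sobel(gray)).mean() / 255.0, 1.0),
            coher.mean(),
            (px[..., 0] - px[..., 1]).mean() / 255.0,
            (px[..., 1] - px[..., 2]).mean() / 255.0,
            (q90 - q10) / 255.0,
        ]
    )


def patch_feature_matrix(patches) -> np.ndarray:
    """Stack patch features for a sequence of Patch objects or arrays."""
    rows = []
    for p in patches:
        pixels = p.pixels if hasattr(p, "pixels") else p
        rows.append(patch_features(pixels))
    return np.asarray(rows)


PIXEL_FEATURE_NAMES = (
    "lum",
    "local_std",
    "dark_density",
    "dark_patchiness",
    "edge_energy",
    "coherence",
    "red_green",
    "green_blue",
)


def pixel_features(pixels: np.ndarray, window: int = 15) -> np.ndarray:
    """Per-pixel feature stack (H, W, F) of windowed local statistics."""
    px = np.asarray(pixels, dtype=float)
    gray = _luminance(px)
    mean = uniform_filter(gray, size=window)
    sq = uniform_filter(gray * gray, size=window)
    local_std = np.sqrt(np.maximum(sq - mean * mean, 0.0))
    dark = (gray < DARK_LEVEL).astype(float)
    dark_density = uniform_filter(dark, size=window)
    fine_dark = uniform_filter(dark, size=5)
    m2 = uniform_filter(fine_dark * fine_dark, size=window)
    m1 = uniform_filter(fine_dark, size=window)
    patchiness = np.sqrt(np.maximum(m2 - m1 * m1, 0.0))
    edge = uniform_filter(np.abs(sobel(gray)), size=window) / 255.0
    coher = uniform_filter(_structure_tensor_coherence(gray, 2.0), size=window)
    rg = uniform_filter(px[..., 0] - px[..., 1], size=window) / 255.0
    gb = uniform_filter(px[..., 1] - px[..., 2], size=window) / 255.0
    return np.stack(
        [mean / 255.0, local_std / 255.0, dark_density, patchiness, edge, coher, rg, gb],
        axis=-1,
    )
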