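"""Foreground detection and patch extraction.

Patches are sampled uniformly over admissible top-left positions with
rejection against two fraction filters: a minimum tissue fraction (the
"majority of tissue" rule, default 0.5) and an optional minimum tumor
fraction (0.66 for the mutation tasks that restrict to predicted tumor).
"Magnification" is simulated by integer-factor resampling of the base
raster: a "20x" patch from a 1.0 micron-per-pixel slide is cut from the
2x-upsampled image.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from skimage.filters import threshold_otsu

from .types import (
    CLASS_INDEX,
    TUMOR_CLASSES,
    ForegroundMask,
    Patch,
    SlideImage,
)
from .synthcohort import LUMINANCE_WEIGHTS

#: rejection-sampling attempt budget per requested patch
ATTEMPT_FACTOR = 50


def grayscale(pixels: np.ndarray) -> np.ndarray:
    """Standard luminance combination of an RGB raster (float, 0-255)."""
    return np.asarray(pixels, dtype=float) @ LUMINANCE_WEIGHTS


def otsu_foreground(slide: SlideImage) -> ForegroundMask:
    """Separate tissue foreground from bright glass background.

    The threshold maximizes inter-class variance of the grayscale histogram;
    pixels on the darker side are tissue.  A constant image has no defined
    threshold: returns an all-background mask with a warning.
    """
    gray = grayscale(slide.pixels)
    lo, hi = gray.min(), gray.max()
    if lo == hi:
        warnings.warn("constant image: Otsu threshold undefined, all background")
        return ForegroundMask(mask=np.zeros(gray.shape, dtype=np.uint8), threshold=lo)
    g8 = gray.astype(np.uint8)
    cut = float(threshold_otsu(g8, nbins=256))
    # report the midpoint of the empty gap between the two classes; the mask
    # is identical for any threshold inside the gap
    above = g8[g8 > cut]
    thr = 0.5 * (cut + (above.min() if above.size else 255.0))
    return ForegroundMask(mask=(g8 <= cut).astype(np.uint8), threshold=thr)


def patch_fractions(
    top_left: tuple[int, int],
    size_px: int,
    mask: np.ndarray,
    labelmap: np.ndarray | None = None,
) -> tuple[float, float | None]:
    """(tissue_fraction, tumor_fraction) of one patch region.

    tissue_fraction counts foreground mask pixels / size^2; tumor_fraction
    counts tumor-class pixels of the label map (FP_like, FN_like, and
    mutant_like) and is None when no label map is given.
    """
    r, c = top_left
    if r < 0 or c < 0 or r + size_px > mask.shape[0] or c + size_px > mask.shape[1]:
        raise ValueError("patch region outside bounds")
    window = mask[r : r + size_px, c : c + size_px]
    tissue = float(window.sum()) / size_px**2
    tumor = None
    if labelmap is not None:
        lab = labelmap[r : r + size_px, c : c + size_px]
        tumor_codes = [CLASS_INDEX[name] for name in TUMOR_CLASSES]
        tumor = float(np.isin(lab, tumor_codes).sum()) / size_px**2
    return tissue, tumor


def _magnified(slide: SlideImage, magnification_tag: str) -> tuple[np.ndarray, int]:
    """Raster at the requested magnification plus the scale factor used."""
    if magnification_tag == "10x":
        target_mpp = 1.0
    elif magnification_tag == "20x":
        target_mpp = 0.5
    else:
        raise ValueError(f"unknown magnification tag {magnification_tag!r}")
    factor = slide.mpp / target_mpp
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"cannot resample mpp {slide.mpp} to {magnification_tag} by an "
            "integer factor"
        )
    factor = int(round(factor))
    if factor == 1:
        return slide.pixels, 1
    up = np.repeat(np.repeat(slide.pixels, factor, axis=0), factor, axis=1)
    return up, factor


def extract_patches(
    slide: SlideImage,
    mask: ForegroundMask | np.ndarray,
    size_px: int,
    magnification_tag: str = "10x",
    n_patches: int = 100,
    min_tissue_fraction: float = 0.5,
    min_tumor_fraction: float = 0.0,
    seed: int = 0,
    labelmap: np.ndarray | None = None,
) -> list[Patch]:
    """Uniformly sample patches passing the tissue/tumor fraction filters.

    Top-left coordinates are drawn uniformly over all in-bounds positions (at
    base resolution) and rejected until ``n_patches`` pass or the attempt
    budget (50 per requested patch) is exhausted, in which case fewer patches
    are returned with a warning.  Deterministic given ``seed``.
    """
    mask_arr = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask)
    raster, factor = _magnified(slide, magnification_tag)
    base_size = size_px / factor
    if base_size != int(base_size):
        raise ValueError("size_px must be divisible by the magnification factor")
    base_size = int(base_size)
    h, w = mask_arr.shape
    if base_size > min(h, w):
        raise ValueError("patch size exceeds slide bounds")
    if not (0 <= min_tissue_fraction <= 1 and 0 <= min_tumor_fraction <= 1):
        raise ValueError("fraction filters outside [0, 1]")

    rng = np.random.default_rng(seed)
    patches: list[Patch] = []
    budget = ATTEMPT_FACTOR * n_patches
    for _ in range(budget):
        if len(patches) >= n_patches:
            break
        r = int(rng.integers(0, h - base_size + 1))
        c = int(rng.integers(0, w - base_size + 1))
        tissue, tumor = patch_fractions((r, c), base_size, mask_arr, labelmap)
        if tissue < min_tissue_fraction:
            continue
        if min_tumor_fraction > 0 and (tumor is None or tumor < min_tumor_fraction):
            continue
        rr, cc = r * factor, c * factor
        patches.append(
            Patch(
                slide_id=slide.slide_id,
                top_left=(r, c),
                size_px=size_px,
                magnification_tag=magnification_tag,
                tissue_fraction=tissue,
                tumor_fraction=tumor,
                pixels=raster[rr : rr + size_px, cc : cc + size_px].copy(),
            )
        )
    if len(patches) < n_patches:
        warnings.warn(
            f"attempt budget exhausted: {len(patches)}/{n_patches} patches "
            f"for slide {slide.slide_id}"
        )
    return patches


def admissible_positions(
    mask: np.ndarray,
    size_px: int,
    min_tissue_fraction: float,
    labelmap: np.ndarray | None = None,
    min_tumor_fraction: float = 0.0,
) -> list[tuple[int, int]]:
    """Enumerate every top-left position passing the fraction filters."""
    h, w = mask.shape
    out = []
    for r in range(h - size_px + 1):
        for c in range(w - size_px + 1):
            tissue, tumor = patch_fractions((r, c), size_px, mask, labelmap)
            if tissue < min_tissue_fraction:
                continue
            if min_tumor_fraction > 0 and (tumor is None or tumor < min_tumor_fraction):
                continue
            out.append((r, c))
    return out


def grid_patches(
    slide: SlideImage,
    mask: ForegroundMask | np.ndarray,
    size_px: int,
    stride: int,
    min_tissue_fraction: float = 0.5,
    labelmap: np.ndarray | None = None,
) -> list[Patch]:
    """Overlapping grid tiling (used for TMA cores: 240 px at stride 120).

    Windows are placed every ``stride`` pixels, with a final row/column
    clamped to the slide edge so the tissue disk is fully covered.
    """
    mask_arr = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask)
    h, w = mask_arr.shape
    if size_px > min(h, w):
        raise ValueError("patch size exceeds slide bounds")
    rows = sorted({min(r, h - size_px) for r in range(0, h, stride)})
    cols = sorted({min(c, w - size_px) for c in range(0, w, stride)})
    patches = []
    for r in rows:
        for c in cols:
            tissue, tumor = patch_fractions((r, c), size_px, mask_arr, labelmap)
            if tissue < min_tissue_fraction:
                continue
            patches.append(
                Patch(
                    slide_id=slide.slide_id,
                    top_left=(r, c),
                    size_px=size_px,
                    magnification_tag="10x" if slide.mpp == 1.0 else "20x",
                    tissue_fraction=tissue,
                    tumor_fraction=tumor,
                    pixels=slide.pixels[r : r + size_px, c : c + size_px].copy(),
                )
            )
    return patches


def patch_manifest(patches: list[Patch]):
    """Patch bookkeeping as a DataFrame (one row per patch)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "slide_id": [p.slide_id for p in patches],
            "row": [p.top_left[0] for p in patches],
            "col": [p.top_left[1] for p in patches],
            "size": [p.size_px for p in patches],
            "magnification": [p.magnification_tag for p in patches],
            "tissue_fraction": [p.tissue_fraction for p in patches],
            "tumor_fraction": [p.tumor_fraction for p in patches],
        }
    )
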