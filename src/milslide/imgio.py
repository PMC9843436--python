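"""Reading and writing the pipeline's on-disk formats.

Slides, cores, and patches are 8-bit RGB PNG (or TIFF); label maps are
single-channel palette PNG with one palette entry per class index; tabular
outputs are CSV written by pandas elsewhere.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .types import CLASS_ORDER, SlideImage

#: display palette for label maps, one RGB entry per class index
LABEL_PALETTE = [
    (255, 255, 255),  # background
    (31, 119, 180),   # FP_like
    (44, 160, 44),    # FN_like
    (255, 127, 14),   # stroma
    (127, 127, 127),  # necrosis
    (214, 39, 40),    # mutant_like
    (148, 103, 189),  # normal
]


def save_rgb(path: str | Path, pixels: np.ndarray) -> None:
    """Write an (H, W, 3) uint8 raster as PNG/TIFF (by extension)."""
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="RGB").save(path)


def load_rgb(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_slide(path: str | Path, slide: SlideImage) -> None:
    save_rgb(path, slide.pixels)


def load_slide(path: str | Path, mpp: float = 1.0) -> SlideImage:
    return SlideImage(pixels=load_rgb(path), mpp=mpp, slide_id=Path(path).stem)


def save_labelmap(path: str | Path, labels: np.ndarray) -> None:
    """Write a class-index map as a palette PNG."""
    img = Image.fromarray(np.asarray(labels, dtype=np.uint8), mode="P")
    palette = []
    for i in range(256):
        palette.extend(LABEL_PALETTE[i] if i < len(LABEL_PALETTE) else (0, 0, 0))
    img.putpalette(palette)
    img.save(path)


def load_labelmap(path: str | Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode not in ("P", "L"):
        raise ValueError("label map must be a single-channel/palette image")
    arr = np.asarray(img, dtype=np.uint8)
    if arr.max() >= len(CLASS_ORDER):
        raise ValueError("label value outside the class vocabulary")
    return arr
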