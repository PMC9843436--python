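"""Core value types shared across the pipeline.

Conventions used everywhere in this package:

* rasters are ``numpy`` arrays indexed ``[row, col]`` (0-based), RGB rasters
  are ``uint8`` of shape ``(H, W, 3)``, label maps are integer arrays of the
  same height/width;
* patch coordinates are the top-left ``(row, col)`` of a half-open
  ``size_px x size_px`` window;
* class labels are strings drawn from :data:`CLASS_ORDER` plus the auxiliary
  ``"normal"`` texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed class vocabulary for label maps and segmentation outputs.  Index in
#: this list == integer code in a label map.  ``mutant_like`` and ``normal``
#: extend the five segmentation classes.
CLASS_ORDER: tuple[str, ...] = (
    "background",
    "FP_like",
    "FN_like",
    "stroma",
    "necrosis",
    "mutant_like",
    "normal",
)

#: The five classes the tissue segmenter is trained on.
SEG_CLASS_ORDER: tuple[str, ...] = CLASS_ORDER[:5]

#: Classes counted as tumor for tumor-fraction filters.
TUMOR_CLASSES: tuple[str, ...] = ("FP_like", "FN_like", "mutant_like")

CLASS_INDEX: dict[str, int] = {name: i for i, name in enumerate(CLASS_ORDER)}


@dataclass
class SlideImage:
    """An RGB raster with a resolution tag.

    ``mpp`` is microns per pixel: 1.0 corresponds to the "10x" magnification
    convention, 0.5 to "20x".
    """

    pixels: np.ndarray
    mpp: float = 1.0
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("SlideImage.pixels must be an (H, W, 3) raster")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("empty raster")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ForegroundMask:
    """Binary tissue mask produced by Otsu thresholding (1 = tissue)."""

    mask: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(np.uint8)
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be 0/1")
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold must be in [0, 255]")


@dataclass
class Patch:
    """A fixed-size crop of a slide with its bookkeeping.

    ``tumor_fraction`` is ``None`` when no label map was available to
    compute it.
    """

    slide_id: str
    top_left: tuple[int, int]
    size_px: int
    magnification_tag: str
    tissue_fraction: float
    tumor_fraction: float | None
    pixels: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.tissue_fraction <= 1.0:
            raise ValueError("tissue_fraction outside [0, 1]")
        if self.tumor_fraction is not None and not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction outside [0, 1]")


@dataclass
class PatchPrediction:
    """Per-class probabilities for one patch."""

    scores: np.ndarray
    patch: Patch | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.min() < -1e-9 or self.scores.max() > 1 + 1e-9:
            raise ValueError("scores outside [0, 1]")
        if abs(self.scores.sum() - 1.0) > 1e-6:
            raise ValueError("scores must sum to 1")

    @property
    def argmax_class(self) -> int:
        return int(np.argmax(self.scores))


@dataclass
class SlidePrediction:
    """Slide-level aggregation of patch calls into a positive ratio."""

    slide_id: str
    n_patches: int
    n_positive: int
    positive_ratio: float
    call: str | None = None
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        if self.n_patches < 1:
            raise ValueError("need at least one patch")
        expected = self.n_positive / self.n_patches
        if abs(self.positive_ratio - expected) > 1e-12:
            raise ValueError("positive_ratio != n_positive / n_patches")


@dataclass
class SurvivalRecord:
    """Right-censored time-to-event record with an optional hazard score."""

    subject_id: str
    time: float
    event: int
    hazard: float | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0/1")
        if self.hazard is not None and not -1.0 <= self.hazard <= 1.0:
            raise ValueError("hazard outside [-1, 1]")


@dataclass
class RiskGroupCutoffs:
    """Pair of hazard cutoffs partitioning subjects into three risk groups.

    hazard <= C_L -> low; C_L < hazard <= C_H -> intermediate; else high.
    """

    c_low: float
    c_high: float

    def __post_init__(self) -> None:
        if not self.c_low < self.c_high:
            raise ValueError("require C_L < C_H")

    def assign(self, hazards: np.ndarray) -> np.ndarray:
        """Return group index per hazard: 0=low, 1=intermediate, 2=high."""
        h = np.asarray(hazards, dtype=float)
        return np.where(h <= self.c_low, 0, np.where(h <= self.c_high, 1, 2))


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if s.size and (np.diff(s) > 1e-12).any():
            raise ValueError("survival must be non-increasing")


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows are truth, columns are predictions."""

    counts: np.ndarray
    class_order: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class BinomialAgreement:
    """Exact binomial point estimate and Clopper-Pearson interval (percent)."""

    successes: int
    trials: int
    point_pct: float
    ci_low_pct: float
    ci_high_pct: float

    def __post_init__(self) -> None:
        if not 0 <= self.successes <= self.trials:
            raise ValueError("successes must be in [0, trials]")
        if not self.ci_low_pct - 1e-9 <= self.point_pct <= self.ci_high_pct + 1e-9:
            raise ValueError("point estimate outside its interval")

    def rounded(self) -> tuple[int, int, int]:
        """(point, low, high) rounded half-up to integer percent."""
        from .evalstats import round_half_up

        return (
            round_half_up(self.point_pct),
            round_half_up(self.ci_low_pct),
            round_half_up(self.ci_high_pct),
        )
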