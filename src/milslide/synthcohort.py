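"""Synthetic slide, TMA, and cohort generation.

The generator emulates the statistical structure the downstream analysis
relies on, not histologic realism:

* each tissue class is a *texture* — a stained base color, Poisson-scattered
  dark elliptical blobs (nucleus proxies), and oriented band noise — so that
  classes are separable by locally computable statistics (mean luminance,
  dark-blob density/scale, orientation coherence);
* background is bright ("glass"), so Otsu thresholding separates it;
* slide-level mutation status is realized as a *mixture*: a fraction of the
  tumor area (``mutant_fraction``, the stand-in for variant allele fraction)
  is re-textured with the ``mutant_like`` class, planted as spatially
  contiguous disks to emulate subclonal regions;
* survival times are exponential with rate
  ``baseline_rate * exp(coef * centered mutant_fraction)``, censored by an
  independent exponential and a follow-up cap, so closed-form checks exist.

All randomness flows from one integer seed through a named
``numpy.random.Generator``; every generator is a pure function of its spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .types import CLASS_INDEX, CLASS_ORDER, SlideImage, SurvivalRecord

LUMINANCE_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Color of the nucleus-proxy blobs (dark hematoxylin-like purple).
BLOB_COLOR = np.array([64.0, 44.0, 104.0])


@dataclass(frozen=True)
class TextureClassParams:
    """Parameters of one synthetic texture class.

    spot_density is the expected number of nucleus-like blobs per 10^4 px^2;
    anisotropy in [0, 1] controls how strongly blob orientations and band
    noise align with a shared region orientation.
    """

    class_name: str
    base_color: tuple[int, int, int]
    spot_density: float
    spot_radius_px: float
    anisotropy: float
    noise_sd: float

    @property
    def base_luminance(self) -> float:
        return float(LUMINANCE_WEIGHTS @ np.asarray(self.base_color, dtype=float))


#: Default texture palette.  Tissue classes are pairwise separated by a wide
#: margin in at least one of spot_density / spot_radius_px / anisotropy, and
#: the background is far brighter than any tissue class.
DEFAULT_PALETTE: dict[str, TextureClassParams] = {
    p.class_name: p
    for p in [
        TextureClassParams("background", (242, 240, 245), 0.0, 0.0, 0.0, 2.0),
        TextureClassParams("FP_like", (168, 120, 170), 55.0, 2.0, 0.1, 6.0),
        TextureClassParams("FN_like", (190, 140, 180), 14.0, 4.0, 0.1, 6.0),
        TextureClassParams("stroma", (214, 168, 196), 4.0, 1.5, 0.92, 7.0),
        TextureClassParams("necrosis", (204, 178, 162), 1.0, 2.0, 0.0, 16.0),
        TextureClassParams("mutant_like", (150, 100, 150), 110.0, 2.6, 0.1, 6.0),
        TextureClassParams("normal", (206, 172, 204), 7.0, 1.2, 0.55, 5.0),
    ]
}


def validate_palette(
    palette: dict[str, TextureClassParams], margin: float = 0.25
) -> None:
    """Check the palette invariants.

    The background must be strictly brighter than every tissue class, and any
    two tissue classes must differ by a relative ``margin`` in at least one
    of spot_density, spot_radius_px, or anisotropy (absolute for anisotropy).
    """
    bg = palette["background"]
    tissue = [p for n, p in palette.items() if n != "background"]
    for p in tissue:
        if p.base_luminance >= bg.base_luminance:
            raise ValueError(f"{p.class_name} is not darker than background")
    for i, a in enumerate(tissue):
        for b in tissue[i + 1 :]:
            rel = lambda x, y: abs(x - y) / max(x, y, 1e-9)
            if (
                rel(a.spot_density, b.spot_density) < margin
                and rel(a.spot_radius_px, b.spot_radius_px) < margin
                and abs(a.anisotropy - b.anisotropy) < margin
            ):
                raise ValueError(
                    f"classes {a.class_name}/{b.class_name} are not separated"
                )


validate_palette(DEFAULT_PALETTE)


@dataclass
class SyntheticSlideSpec:
    """Layout and mixing recipe for one synthetic slide.

    region_layout is a list of ``(vertices, class_name)`` where vertices is
    an ``(n, 2)`` array of (row, col) polygon corners.  Uncovered canvas is
    background; regions must not overlap.  ``mutant_fraction`` is the target
    share of tumor pixels re-textured as ``mutant_like``.
    """

    width_px: int
    height_px: int
    region_layout: list[tuple[np.ndarray, str]]
    mutant_fraction: float = 0.0
    seed: int = 0
    palette: dict[str, TextureClassParams] = field(
        default_factory=lambda: DEFAULT_PALETTE
    )

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("zero-area canvas")
        if not 0.0 <= self.mutant_fraction <= 1.0:
            raise ValueError("mutant_fraction outside [0, 1]")


def rect(r0: int, c0: int, r1: int, c1: int) -> np.ndarray:
    """(row, col) corner array of the half-open rectangle [r0:r1, c0:c1]."""
    return np.array([[r0, c0], [r0, c1 - 1], [r1 - 1, c1 - 1], [r1 - 1, c0]])


def _render_class(
    canvas: np.ndarray,
    mask: np.ndarray,
    params: TextureClassParams,
    rng: np.random.Generator,
) -> None:
    """Render one class texture into ``canvas`` over ``mask`` (in place)."""
    h, w = mask.shape
    area = int(mask.sum())
    if area == 0:
        return
    canvas[mask] = np.asarray(params.base_color, dtype=float)

    # oriented band noise: a shared region orientation phi; amplitude grows
    # with anisotropy so coherent stripes are a measurable signature
    phi = rng.uniform(0, math.pi)
    if params.anisotropy > 0:
        rr, cc = np.nonzero(mask)
        wavelength = 7.0
        phase = rng.uniform(0, 2 * math.pi)
        proj = (rr * math.sin(phi) + cc * math.cos(phi)) * (2 * math.pi / wavelength)
        bands = (params.anisotropy * 14.0) * np.sin(proj + phase)
        canvas[rr, cc] += bands[:, None]

    # Poisson-scattered elliptical blobs, orientation-coherent per anisotropy
    n_blobs = rng.poisson(params.spot_density * area / 1e4)
    if n_blobs > 0 and params.spot_radius_px > 0:
        flat = np.flatnonzero(mask.ravel())
        centers = flat[rng.integers(0, flat.size, size=n_blobs)]
        for idx in centers:
            r0, c0 = divmod(int(idx), w)
            rad = max(0.6, rng.normal(params.spot_radius_px, 0.2 * params.spot_radius_px))
            theta = phi + (1.0 - params.anisotropy) * rng.uniform(
                -math.pi / 2, math.pi / 2
            )
            rr, cc = draw_ellipse(r0, c0, rad, 0.6 * rad, shape=(h, w), rotation=theta)
            keep = mask[rr, cc]
            rr, cc = rr[keep], cc[keep]
            shade = BLOB_COLOR + rng.normal(0.0, 8.0, size=3)
            canvas[rr, cc] = shade

    if params.noise_sd > 0:
        rr, cc = np.nonzero(mask)
        canvas[rr, cc] += rng.normal(0.0, params.noise_sd, size=(rr.size, 3))


def _plant_mutant(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> None:
    """Re-label contiguous disks of tumor pixels as mutant_like (in place)."""
    tumor = (labels == CLASS_INDEX["FP_like"]) | (labels == CLASS_INDEX["FN_like"])
    n_tumor = int(tumor.sum())
    if fraction <= 0 or n_tumor == 0:
        return
    target = fraction * n_tumor
    # disk area ~1.5% of tumor area keeps overshoot well inside +-0.05
    radius = min(25.0, max(2.0, math.sqrt(0.015 * n_tumor / math.pi)))
    mutant = np.zeros_like(tumor)
    eligible = np.flatnonzero((tumor & ~mutant).ravel())
    w = labels.shape[1]
    for _ in range(100000):
        if mutant.sum() >= target or eligible.size == 0:
            break
        idx = int(eligible[rng.integers(0, eligible.size)])
        r0, c0 = divmod(idx, w)
        rr, cc = draw_disk((r0, c0), radius, shape=labels.shape)
        keep = tumor[rr, cc]
        mutant[rr[keep], cc[keep]] = True
        eligible = np.flatnonzero((tumor & ~mutant).ravel())
    labels[mutant] = CLASS_INDEX["mutant_like"]


def generate_slide(spec: SyntheticSlideSpec) -> tuple[SlideImage, np.ndarray]:
    """Render a synthetic slide and its pixel ground-truth label map.

    Deterministic given ``spec.seed``.  Returns ``(SlideImage, labels)`` with
    ``labels`` the same height/width, values indexing :data:`CLASS_ORDER`.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    labels = np.zeros((h, w), dtype=np.uint8)
    covered = np.zeros((h, w), dtype=bool)
    for vertices, class_name in spec.region_layout:
        if class_name not in spec.palette:
            raise ValueError(f"unknown texture class {class_name!r}")
        vertices = np.asarray(vertices)
        rr, cc = draw_polygon(vertices[:, 0], vertices[:, 1], shape=(h, w))
        if covered[rr, cc].any():
            raise ValueError("region layout overlaps")
        covered[rr, cc] = True
        labels[rr, cc] = CLASS_INDEX[class_name]

    _plant_mutant(labels, spec.mutant_fraction, rng)

    canvas = np.empty((h, w, 3), dtype=float)
    for name in CLASS_ORDER:
        mask = labels == CLASS_INDEX[name]
        if mask.any():
            _render_class(canvas, mask, spec.palette[name], rng)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return SlideImage(pixels=pixels, mpp=1.0), labels


def default_layout(
    height_px: int, width_px: int, class_name: str, rng: np.random.Generator
) -> list[tuple[np.ndarray, str]]:
    """A simple slide layout: background margin around a tissue block.

    Tumor-class slides get a stroma strip and a necrosis pocket alongside the
    tumor block; non-tumor slides are a single block of their class.
    """
    m = max(4, height_px // 10)
    r0, r1 = m, height_px - m
    c0, c1 = m, width_px - m
    if class_name in ("FP_like", "FN_like"):
        split = c0 + int(0.72 * (c1 - c0))
        nec_r = r0 + int(0.65 * (r1 - r0))
        return [
            (rect(r0, c0, r1, split), class_name),
            (rect(r0, split, nec_r, c1), "stroma"),
            (rect(nec_r, split, r1, c1), "necrosis"),
        ]
    return [(rect(r0, c0, r1, c1), class_name)]


@dataclass
class SurvivalParams:
    """Exponential survival generator settings (rates per year)."""

    baseline_rate: float = 0.2
    log_hazard_coefficient: float = 0.0
    censoring_rate: float = 0.05
    max_followup_years: float = 20.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.censoring_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.max_followup_years <= 0:
            raise ValueError("max_followup_years must be positive")


@dataclass
class SyntheticCohortSpec:
    """Recipe for a cohort of synthetic slides with labels and survival."""

    n_slides: int
    class_balance: dict[str, float]
    mutant_prevalence: float = 0.0
    mutant_fraction_distribution: tuple = ("uniform", 0.3, 0.7)
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    seed: int = 0
    slide_px: int = 160
    palette: dict[str, TextureClassParams] = field(
        default_factory=lambda: DEFAULT_PALETTE
    )

    def __post_init__(self) -> None:
        total = sum(self.class_balance.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("class_balance proportions must sum to 1")
        if not 0.0 <= self.mutant_prevalence <= 1.0:
            raise ValueError("mutant_prevalence outside [0, 1]")


@dataclass
class CohortSlide:
    """One generated cohort member: raster, truth, and survival labels."""

    slide: SlideImage
    labels: np.ndarray
    class_name: str
    mutant: int
    mutant_fraction: float
    record: SurvivalRecord


def _draw_fraction(dist: tuple, rng: np.random.Generator) -> float:
    kind = dist[0]
    if kind == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    if kind == "beta":
        return float(rng.beta(dist[1], dist[2]))
    if kind == "fixed":
        return float(dist[1])
    raise ValueError(f"unknown distribution {kind!r}")


def _fraction_stats(dist: tuple, prevalence: float) -> tuple[float, float]:
    """Mean and SD of the mutant-fraction mixture (zero for non-mutants)."""
    kind = dist[0]
    if kind == "uniform":
        mu_d = 0.5 * (dist[1] + dist[2])
        var_d = (dist[2] - dist[1]) ** 2 / 12.0
    elif kind == "beta":
        a, b = dist[1], dist[2]
        mu_d = a / (a + b)
        var_d = a * b / ((a + b) ** 2 * (a + b + 1))
    elif kind == "fixed":
        mu_d, var_d = float(dist[1]), 0.0
    else:
        raise ValueError(f"unknown distribution {kind!r}")
    mu = prevalence * mu_d
    var = prevalence * (var_d + mu_d**2) - mu**2
    return mu, math.sqrt(max(var, 0.0))


def generate_cohort(spec: SyntheticCohortSpec) -> list[CohortSlide]:
    """Generate a cohort of slides with class, mutation, and survival labels.

    The planted risk feature is the slide's mutant_fraction, standardized to
    zero mean and unit variance over the cohort's mixture distribution, so
    ``log_hazard_coefficient`` is a conventional per-SD log hazard ratio:
    the event hazard is ``baseline_rate * exp(coefficient * feature)``, and
    with coefficient 0 the image feature and the event time are independent
    by construction.
    """
    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.class_balance)
    probs = np.array([spec.class_balance[c] for c in classes])
    sv = spec.survival
    center, scale = _fraction_stats(
        spec.mutant_fraction_distribution, spec.mutant_prevalence
    )

    out: list[CohortSlide] = []
    for i in range(spec.n_slides):
        class_name = str(rng.choice(classes, p=probs))
        is_tumor = class_name in ("FP_like", "FN_like")
        mutant = int(is_tumor and rng.random() < spec.mutant_prevalence)
        frac = _draw_fraction(spec.mutant_fraction_distribution, rng) if mutant else 0.0

        slide_seed = int(rng.integers(0, 2**31 - 1))
        slide_spec = SyntheticSlideSpec(
            width_px=spec.slide_px,
            height_px=spec.slide_px,
            region_layout=default_layout(spec.slide_px, spec.slide_px, class_name, rng),
            mutant_fraction=frac,
            seed=slide_seed,
            palette=spec.palette,
        )
        slide, labels = generate_slide(slide_spec)
        slide = replace(slide, slide_id=f"S{i:04d}")

        feature = (frac - center) / scale if scale > 0 else 0.0
        rate = sv.baseline_rate * math.exp(sv.log_hazard_coefficient * feature)
        t_event = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        t_cens = (
            rng.exponential(1.0 / sv.censoring_rate)
            if sv.censoring_rate > 0
            else math.inf
        )
        horizon = min(t_cens, sv.max_followup_years)
        time = max(min(t_event, horizon), 1e-6)
        event = int(t_event <= horizon)
        record = SurvivalRecord(subject_id=f"S{i:04d}", time=time, event=event)
        out.append(CohortSlide(slide, labels, class_name, mutant, frac, record))
    return out


def cohort_table(cohort: Sequence[CohortSlide]):
    """Cohort metadata as a DataFrame mirroring the cohort CSV layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "slide_id": [c.slide.slide_id for c in cohort],
            "class": [c.class_name for c in cohort],
            "mutant": [c.mutant for c in cohort],
            "mutant_fraction": [c.mutant_fraction for c in cohort],
            "time_years": [c.record.time for c in cohort],
            "event": [c.record.event for c in cohort],
        }
    )


@dataclass
class TMAPatient:
    """All cores of one TMA patient; cores share the class label."""

    patient_id: str
    class_name: str
    cores: list[SlideImage]
    label_maps: list[np.ndarray]


def generate_tma(
    n_patients: int,
    cores_per_patient: int | Sequence[int],
    core_diameter_px: int,
    spec: SyntheticCohortSpec,
    canvas_margin_px: int = 8,
) -> list[TMAPatient]:
    """Generate TMA core images grouped by patient.

    Duplicate cores of one patient share the patient's ground-truth class but
    are independent texture realizations.  ``cores_per_patient`` may be a
    single integer or one count per patient (e.g. the 126-patient layout with
    duplicates except one patient with four cores -> 254 cores).
    """
    if isinstance(cores_per_patient, int):
        counts = [cores_per_patient] * n_patients
    else:
        counts = list(cores_per_patient)
        if len(counts) != n_patients:
            raise ValueError("need one core count per patient")
    if min(counts) < 1:
        raise ValueError("cores_per_patient must be >= 1")
    canvas_px = core_diameter_px + 2 * canvas_margin_px
    if core_diameter_px > canvas_px:
        raise ValueError("core diameter exceeds canvas")

    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.class_balance)
    probs = np.array([spec.class_balance[c] for c in classes])
    center = (canvas_px - 1) / 2.0
    n_vert = 48
    angles = np.linspace(0, 2 * math.pi, n_vert, endpoint=False)
    radius = core_diameter_px / 2.0
    circle = np.stack(
        [center + radius * np.sin(angles), center + radius * np.cos(angles)], axis=1
    )

    patients: list[TMAPatient] = []
    for p in range(n_patients):
        class_name = str(rng.choice(classes, p=probs))
        cores, maps = [], []
        for c in range(counts[p]):
            core_seed = int(rng.integers(0, 2**31 - 1))
            slide_spec = SyntheticSlideSpec(
                width_px=canvas_px,
                height_px=canvas_px,
                region_layout=[(circle, class_name)],
                seed=core_seed,
                palette=spec.palette,
            )
            img, lab = generate_slide(slide_spec)
            img = replace(img, slide_id=f"P{p:03d}_core{c}")
            cores.append(img)
            maps.append(lab)
        patients.append(TMAPatient(f"P{p:03d}", class_name, cores, maps))
    return patients
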