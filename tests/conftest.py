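"""Shared fixtures: small synthetic slides and cohorts, generated at test
time (no stored image fixtures)."""

from __future__ import annotations

import numpy as np
import pytest

from milslide import synthcohort as sc
from milslide import tiling


def make_slide(class_name: str, seed: int, px: int = 160, mutant_fraction=0.0):
    """One default-layout slide of the given class with its label map."""
    spec = sc.SyntheticSlideSpec(
        width_px=px,
        height_px=px,
        region_layout=sc.default_layout(px, px, class_name, np.random.default_rng(seed)),
        mutant_fraction=mutant_fraction,
        seed=seed,
    )
    return sc.generate_slide(spec)


def pure_patches(class_name: str, seeds, size=32, n=25):
    """Patches drawn entirely from one texture class (patch-level truth)."""
    from milslide.types import CLASS_INDEX

    out = []
    for s in seeds:
        slide, labels = make_slide(class_name, s)
        mask = (labels == CLASS_INDEX[class_name]).astype(np.uint8)
        ps = tiling.extract_patches(
            slide, mask, size, n_patches=n, min_tissue_fraction=0.9, seed=s
        )
        out.extend(p.pixels for p in ps)
    return out


@pytest.fixture(scope="session")
def fn_slide():
    return make_slide("FN_like", seed=7)


@pytest.fixture(scope="session")
def fp_slide():
    return make_slide("FP_like", seed=8)


@pytest.fixture(scope="session")
def mutant_slide():
    return make_slide("FN_like", seed=9, mutant_fraction=0.4)


@pytest.fixture(scope="session")
def three_class_patches():
    """Pure patches for FP_like / FN_like / normal: (train, val, test) dicts."""
    names = ("FP_like", "FN_like", "normal")
    train = {c: pure_patches(c, range(i * 10, i * 10 + 5)) for i, c in enumerate(names)}
    val = {c: pure_patches(c, range(i * 10 + 5, i * 10 + 7)) for i, c in enumerate(names)}
    test = {c: pure_patches(c, range(100 + i * 10, 100 + i * 10 + 3)) for i, c in enumerate(names)}
    return names, train, val, test
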