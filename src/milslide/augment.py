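"""Class balancing by oversampling and geometric augmentation recipes.

A recipe is an ordered subset of the six lossless dihedral ops plus the
original; expanding a base set of ``n`` patches with a recipe of
multiplicity ``m`` yields exactly ``n * m`` patches (the fixed patch-count
arithmetic: 4,000 x 4 = 16,000; 5,200 x 7 = 36,400; 4,000 x 5 = 20,000).
Augmentation happens at dataset assembly, not on the fly, and never changes
a label.  "transpose" is the main-diagonal transpose.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .types import Patch

#: op name -> pixel transform on an (H, W, C) or (H, W) array
OPS = {
    "rot90": lambda a: np.rot90(a, 1),
    "rot180": lambda a: np.rot90(a, 2),
    "rot270": lambda a: np.rot90(a, 3),
    "vflip": lambda a: a[::-1],
    "hflip": lambda a: a[:, ::-1],
    "transpose": lambda a: a.swapaxes(0, 1),
}


@dataclass(frozen=True)
class AugmentationRecipe:
    """Ordered augmentation ops plus whether the original is kept."""

    ops: tuple[str, ...]
    include_original: bool = True

    def __post_init__(self) -> None:
        for op in self.ops:
            if op not in OPS:
                raise ValueError(f"unknown augmentation op {op!r}")
        if len(set(self.ops)) != len(self.ops):
            raise ValueError("duplicate ops in recipe")

    @property
    def multiplicity(self) -> int:
        return len(self.ops) + (1 if self.include_original else 0)


#: the three named recipes with their stated patch arithmetic
RECIPE_ARMS = AugmentationRecipe(("rot90", "vflip", "transpose"))  # x4
RECIPE_NORMAL = AugmentationRecipe(
    ("rot90", "rot180", "rot270", "vflip", "hflip", "transpose")
)  # x7
RECIPE_MUTANT = AugmentationRecipe(("rot90", "rot270", "vflip", "transpose"))  # x5


def augment_array(pixels: np.ndarray, op: str) -> np.ndarray:
    """Apply one named pixel-exact geometric op to a raster."""
    if op not in OPS:
        raise ValueError(f"unknown augmentation op {op!r}")
    return np.ascontiguousarray(OPS[op](pixels))


def augment_patch(patch: Patch, op: str) -> Patch:
    """Transformed copy of a patch; the label is unchanged."""
    return replace(patch, pixels=augment_array(patch.pixels, op))


def expand_with_recipe(base: Sequence, recipe: AugmentationRecipe) -> list:
    """Expand base patches with a recipe: output count = base x multiplicity.

    Ordering is deterministic: all originals first (when kept), then each op
    applied to the whole base set, in recipe order.  Accepts ``Patch``
    objects or bare pixel arrays.
    """
    if len(base) == 0:
        raise ValueError("empty base set")
    out: list = []
    if recipe.include_original:
        out.extend(base)
    for op in recipe.ops:
        for item in base:
            if isinstance(item, Patch):
                out.append(augment_patch(item, op))
            else:
                out.append(augment_array(item, op))
    return out


def oversample_to(patches: Sequence, target_n: int, seed: int = 0) -> list:
    """Oversample to exactly ``target_n`` patches.

    Policy: every patch is taken once (up to ``target_n``), then the
    remainder is drawn with replacement — minimal duplication for a
    minority-class set.  Deterministic given ``seed``.
    """
    if target_n < 0:
        raise ValueError("target_n must be >= 0")
    if len(patches) == 0 and target_n > 0:
        raise ValueError("cannot oversample an empty set")
    rng = np.random.default_rng(seed)
    n = len(patches)
    if target_n <= n:
        idx = rng.permutation(n)[:target_n]
    else:
        extra = rng.integers(0, n, size=target_n - n)
        idx = np.concatenate([rng.permutation(n), extra])
    return [patches[int(i)] for i in idx]


def balance_classes(
    per_class_patches: dict[str, list],
    per_class_recipe: dict[str, AugmentationRecipe] | None = None,
    target_per_class: int | None = None,
    seed: int = 0,
) -> dict[str, list]:
    """Balance classes by recipe expansion and/or oversampling.

    Each class is first expanded with its recipe (if any); when
    ``target_per_class`` is given (default: the maximum expanded class
    count), every class is then over/undersampled to exactly that count.
    """
    expanded = {}
    for name, patches in per_class_patches.items():
        recipe = (per_class_recipe or {}).get(name)
        expanded[name] = expand_with_recipe(patches, recipe) if recipe else list(patches)
    if target_per_class is None:
        target_per_class = max(len(v) for v in expanded.values())
    return {
        name: oversample_to(v, target_per_class, seed=seed + i)
        for i, (name, v) in enumerate(sorted(expanded.items()))
    }
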