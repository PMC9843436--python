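"""Otsu foreground detection, patch tiling, and tissue segmentation.

Trains the pixel segmenter on labeled crops from a few slides, stitches a
whole-slide prediction, and reports IoU overlap with the ground truth.
"""

import numpy as np

from milslide import segment, tiling
from milslide.synthcohort import SyntheticSlideSpec, default_layout, generate_slide

def make_slide(cls, seed):
    rng = np.random.default_rng(seed)
    spec = SyntheticSlideSpec(160, 160, default_layout(160, 160, cls, rng), seed=seed)
    return generate_slide(spec)

def labeled_patches(class_names, seeds, size=32):
    pixels, labels = [], []
    for cls, seed in zip(class_names, seeds):
        slide, lab = make_slide(cls, seed)
        mask = tiling.otsu_foreground(slide)
        print(f"{cls} slide {seed}: Otsu threshold {mask.threshold:.1f}, "
              f"tissue fraction {mask.mask.mean():.2f}")
        for p in tiling.extract_patches(slide, mask, size, n_patches=25,
                                        min_tissue_fraction=0.0, seed=seed):
            r, c = p.top_left
            pixels.append(p.pixels)
            labels.append(np.minimum(lab[r : r + size, c : c + size], 4))
    return pixels, labels

train_px, train_lb = labeled_patches(["FP_like", "FN_like"] * 3, range(6))
val_px, val_lb = labeled_patches(["FP_like", "FN_like"], (10, 11))
config = segment.SegTrainConfig(patch_size=32, epochs=40, seed=0)
model, history = segment.train_segmenter(train_px, train_lb, val_px, val_lb, config)
print(f"\nvalidation loss {history['val_loss'][0]:.3f} -> "
      f"{min(history['val_loss']):.3f} over {len(history['val_loss']) - 1} epochs")

slide, truth = make_slide("FN_like", 20)
seg_map = segment.predict_slide(model, slide, patch_size=32, stride=16)
per_class, mean_iou, weighted_iou = segment.iou_scores(
    seg_map.labels, np.minimum(truth, 4)
)
print(f"stitched whole-slide mean IoU {mean_iou:.3f}, weighted IoU "
      f"{weighted_iou:.3f}")
print("tissue percentages:", {k: round(v, 1)
                              for k, v in segment.tissue_percentages(seg_map).items()})
# Weighted IoU upweights abundant classes, so it exceeds the plain mean
# whenever the dominant tissue class is the best-segmented one.
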