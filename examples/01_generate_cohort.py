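"""Generate a small synthetic cohort and inspect its planted structure.

Each slide is a textured raster with a pixel ground-truth label map; mutant
slides carry contiguous mutant-texture subclones covering a known fraction
of the tumor area (the stand-in for variant allele fraction).
"""

import numpy as np

from milslide.synthcohort import SyntheticCohortSpec, cohort_table, generate_cohort
from milslide.types import CLASS_INDEX

spec = SyntheticCohortSpec(
    n_slides=8,
    class_balance={"FP_like": 0.5, "FN_like": 0.5},
    mutant_prevalence=0.5,
    mutant_fraction_distribution=("uniform", 0.3, 0.7),
    seed=0,
)
cohort = generate_cohort(spec)

print(cohort_table(cohort).to_string(index=False))
print()
for c in cohort:
    if c.mutant:
        tumor = np.isin(
            c.labels, [CLASS_INDEX["FP_like"], CLASS_INDEX["FN_like"],
                       CLASS_INDEX["mutant_like"]]
        )
        share = (c.labels == CLASS_INDEX["mutant_like"]).sum() / tumor.sum()
        print(
            f"{c.slide.slide_id}: planted mutant fraction "
            f"{c.mutant_fraction:.2f}, realized pixel share {share:.2f}"
        )
# The realized mutant pixel share tracks the planted fraction, so the
# slide-level 'mutation' label is a known mixture of patch phenotypes.
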