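"""Tissue saliency on a small phantom cohort with a planted signal.

A scorer whose gradient mass sits on visceral fat stands in for a
trained image model that attends to VAT.  For each tissue class the
cohort table prints the mean observed saliency fraction O (share of
total |gradient|), the expected fraction E (pixel share), their ratio
O/E and the paired t-test p-value.  A ratio above 1 means the model pays
that tissue more attention than its area alone would predict — here VAT
should rank first and the background should fall below 1.
"""

import numpy as np

from ihdrisk import Tissue, class_weighted_scorer, cohort_saliency, image_saliency
from ihdrisk.synth import PhantomSpec, make_phantom

results = []
for seed in range(25):
    slc, mask = make_phantom(
        PhantomSpec(image_size=128, pixel_spacing_mm=(3.0, 3.0), seed=seed)
    )
    scorer = class_weighted_scorer(mask, Tissue.VAT, off_weight=0.1)
    results.append(image_saliency(scorer, slc.pixels, mask))

agg = cohort_saliency(results)
print(f"{'class':>12} {'O':>7} {'E':>7} {'O/E':>6} {'p':>9}")
for cls in agg.ranked_classes():
    name = Tissue(cls).name
    print(
        f"{name:>12} {agg.mean_observed[cls]:7.3f} {agg.mean_expected[cls]:7.3f}"
        f" {agg.ratio[cls]:6.2f} {agg.p_value[cls]:9.2g}"
    )
assert agg.ranked_classes()[0] == int(Tissue.VAT)
print("\nVAT draws the most attention relative to its size, as planted.")
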