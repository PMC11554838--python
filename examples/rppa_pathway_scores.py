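"""RPPA normalization and pathway activity scoring.

Generates a raw RPPA matrix for a paclitaxel-sensitive/-resistant PDX
pair with a planted pathway shift, runs level-3 processing (mouse-
antibody filter, log2, bidirectional median-centering), scores the
planted pathway per sample and compares the groups.
"""

import pandas as pd

from chemoresist import (
    RunConfig, compare_groups, compute_pas, filter_species,
    gen_rppa, log2_transform, median_center_bidirectional,
)

config = RunConfig(seed=42)
raw, truth = gen_rppa(config, shift=1.0)
print(f"raw matrix: {raw.shape[0]} analytes x {raw.shape[1]} samples, scale={raw.scale}")

normalized = median_center_bidirectional(log2_transform(filter_species(raw)))
print(f"after mouse filter + log2 + bidirectional centering: {normalized.shape[0]} analytes")

pathway = truth.pathways[0]
pas = compute_pas(normalized, pathway)
groups = pd.Series(truth.group_labels)
for g in ("sensitive", "resistant"):
    mean = pas.scores[groups[pas.scores.index] == g].mean()
    print(f"mean {pathway.name} PAS in {g} group: {mean:+.2f}")

res = compare_groups(pas.scores, groups, alpha=config.alpha)
print(f"group comparison: {res.test_used}, p = {res.p_value:.2e}")
print("The PAS difference approximates |positive regulators| x planted shift"
      f" = {len(pathway.positive)} x 1.0; a small p confirms the planted activation"
      " is detected through the full normalization chain.")
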