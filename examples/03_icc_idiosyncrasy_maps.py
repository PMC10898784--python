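"""Edgewise ICC idiosyncrasy maps and their condition contrast.

Class-1 ICC across the two scan halves scores each FC edge on being
subject-unique yet temporally stable. Summing a region's incident edge ICCs
gives its ICC strength; comparing the two conditions per RSN shows where the
fingerprint relocates under the drug.
"""

import numpy as np

from connectoprint import (
    SimConfig,
    build_edge_index,
    edge_rsn_labels,
    edgewise_icc,
    fc_pairs_by_condition,
    generate_cohort,
    icc_strength,
    rsn_strength_contrast,
    threshold_icc_matrix,
    zscore_map,
)

cohort = generate_cohort(SimConfig(seed=1))
parc = cohort.parcellation
idx = build_edge_index(parc)
labels = edge_rsn_labels(idx, parc)
pairs = fc_pairs_by_condition(cohort.timeseries)

icc = {cond: edgewise_icc(p, idx) for cond, p in pairs.items()}
for cond, res in icc.items():
    dense = threshold_icc_matrix(res, idx, thr=0.6)
    print(f"{cond}: {int(dense.sum() // 2)} edges with ICC > 0.6 "
          f"(mean edge ICC {res.icc.mean():.3f})")

strength = {cond: icc_strength(res, idx) for cond, res in icc.items()}
contrast = rsn_strength_contrast(strength["psilocybin"], strength["placebo"], parc)
print("\nper-RSN ICC-strength contrast (drug - placebo):")
print(contrast[["rsn", "mean_diff", "t", "p_fdr"]].round(3).to_string(index=False))

z = zscore_map(strength["psilocybin"].strength - strength["placebo"].strength)
top = np.argsort(z)[-3:][::-1]
print("\nregions with the largest z-scored strength increase under the drug:")
for r in top:
    print(f"  {parc.regions[r].label} (z = {z[r]:.2f})")
print("\nIdiosyncrasy concentrates in DMN (and visual) regions under the drug and")
print("in frontoparietal regions under placebo — the fingerprint relocates.")
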