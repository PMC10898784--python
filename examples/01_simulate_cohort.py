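"""Generate a synthetic two-condition cohort and inspect its structure.

The generator produces parcellated BOLD-like time series for 21 drug and 25
placebo subjects (200 cortical regions, 7 resting-state networks), an
11-subscale behavior table for the drug subjects, and the planted ground
truth used by recovery tests.
"""

import numpy as np

from connectoprint import SimConfig, generate_cohort

config = SimConfig(seed=1)
cohort = generate_cohort(config)

n_drug = sum(ts.condition == "psilocybin" for ts in cohort.timeseries)
n_pla = sum(ts.condition == "placebo" for ts in cohort.timeseries)
print(f"cohort: {n_drug} drug + {n_pla} placebo subjects")
print(f"regions: {cohort.parcellation.n_regions} "
      f"({(cohort.parcellation.hemisphere == 'L').sum()} per hemisphere)")
print(f"timepoints per scan: {cohort.timeseries[0].n_timepoints}")

motion_drug = np.mean([ts.motion for ts in cohort.timeseries if ts.condition == "psilocybin"])
motion_pla = np.mean([ts.motion for ts in cohort.timeseries if ts.condition == "placebo"])
print(f"mean motion covariate: drug {motion_drug:.1f} vs placebo {motion_pla:.1f} "
      "(the drug group moves slightly more, as in real pharmacological scans)")

b = np.array(list(cohort.b_true.values()))
print(f"latent intensity b_true: mean {b.mean():.2f}, sd {b.std(ddof=1):.2f} "
      f"across {len(b)} drug subjects")
print(f"planted pattern: {len(cohort.pattern_edge_ids)} edges "
      f"({(cohort.pattern_weights < 0).sum()} negative / "
      f"{(cohort.pattern_weights > 0).sum()} positive weights)")
print("negative weights sit on within-DMN-core and DMN-limbic edges, positive on")
print("DMN-attentional edges: intense experiences lower the former, raise the latter.")
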