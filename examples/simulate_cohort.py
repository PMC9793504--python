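"""Generate a synthetic cohort and inspect its composition.

Draws 3053 individuals from the six-archetype generator, applies the
minimum-observations inclusion rule and prints the calibration figures:
the retained count, the nonresponse share among retained person-wave
cells, and the share of retained individuals who never use a nursing home.
"""

import pandas as pd

import caretraj as ct

cohort, latent = ct.generate_cohort(ct.default_config(), seed=1)
kept, retained, excluded = ct.filter_min_observations(cohort, min_obs=6)
summary = ct.summarize_cohort(kept)

print(f"simulated {cohort.n} individuals; {kept.n} retained "
      f"({100 * kept.n / cohort.n:.1f}%), {len(excluded)} excluded")
print(f"nonresponse share among retained cells: "
      f"{100 * summary['nonresponse_share']:.2f}%")
print(f"never used a nursing home: "
      f"{100 * summary['never_above_none']['nursing_home']:.1f}%")

shares = pd.Series(latent, index=cohort.ids).loc[kept.ids].value_counts(normalize=True)
print("\nlatent archetype shares among retained individuals (%):")
print((100 * shares).round(2).to_string())
# The retained count sits near 74.4% of recruitment and the dominant
# archetype (constant low utilization) holds roughly 83% of the sample.
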