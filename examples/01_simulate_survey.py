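"""Simulate a survey-structured dataset and summarize it.

Generates women nested in enumeration-area clusters nested in divisions,
with covariate marginals matching the published sample table and both binary
outcomes drawn from the shared-random-intercept logistic model, then prints
the descriptive summary. Run: python examples/01_simulate_survey.py
"""

import jointglmm as jg

# a desk-scale version of the survey: 7 divisions x 8 clusters x 25 women
config = jg.SimConfig(n_divisions=7, clusters_per_division=8,
                      women_per_cluster=25, seed=2011)
data = jg.generate_dataset(config)

print(f"simulated {len(data)} women in {data.cluster_id.nunique()} clusters "
      f"across {data.division_id.nunique()} divisions\n")
print(jg.descriptive_summary(data).to_string(index=False))
print("\nEach 'percent' column is the share of women at that level of the "
      "variable; contraceptive use (y_cuc) should sit near 60% and HIV "
      "knowledge (y_hiv) near 70%, the prevalences of the emulated survey.")
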