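"""Calibration, variance-component tests and division ranking.

Runs the assessment steps on one simulated survey: a Hosmer-Lemeshow
calibration test of the pooled standard logistic fit, a boundary-mixture
likelihood-ratio test of the division variance, and the empirical-Bayes
ranking of divisions by their predicted random effect.
Run: python examples/03_diagnostics.py  (about a minute)
"""

import numpy as np
from scipy.special import expit

import jointglmm as jg

config = jg.SimConfig(7, 6, 25, seed=42)
data = jg.generate_dataset(config)
covs = ("age", "education", "tv", "urban")

# 1. Hosmer-Lemeshow on the standard (no random effects) fit
std_spec = jg.ModelSpec.standard("cuc", covs)
std_design = jg.build_stacked_design(data, std_spec)
std_fit = jg.fit(std_design)
phat = expit(std_design.X @ std_fit.params.beta[0])
hl = jg.hosmer_lemeshow(std_design.y, phat, groups=10)
print(f"Hosmer-Lemeshow: chi2={hl.statistic:.3f}, df={hl.df}, p={hl.p:.3f}")
print("  (large chi2 / small p flags miscalibration of the pooled "
      "logistic fit)\n")

# 2. boundary LRT: does the division variance differ from zero?
full = jg.fit(jg.build_stacked_design(
    data, jg.ModelSpec("cuc", covs, ("cluster", "division"), quadrature_order=5)),
    compute_information=False)
reduced = jg.fit(jg.build_stacked_design(
    data, jg.ModelSpec("cuc", covs, ("cluster",), quadrature_order=5)),
    compute_information=False)
lrt = jg.lrt_variance_component(full, reduced)
print(f"LRT for sigma^2_division: stat={lrt.statistic:.3f}, p={lrt.p:.4f}")
print("  (p from the 50:50 chi2_0:chi2_1 mixture, because the null variance "
      "sits on the boundary)\n")

# 3. empirical-Bayes division ranking from the joint model
joint = jg.fit(jg.build_stacked_design(
    data, jg.ModelSpec.joint(covs, order=5)))
effects = jg.predict_random_effects(
    joint, jg.build_stacked_design(data, joint.spec))
print("divisions ranked by predicted random effect (posterior modes):")
print(effects.ranked_divisions().round(4).to_string())
print("\nPositive values are divisions whose women use contraception / know "
      "about HIV more than their covariates explain.")
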