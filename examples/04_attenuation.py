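"""Spillover: how joint modeling changes covariate effects.

When the two outcomes share a woman-level latent intercept, per-outcome
models that ignore it estimate attenuated (marginal) slopes, while the joint
model recovers the conditional ones. This script simulates both regimes
(shared variance on/off) and prints the aligned comparison table.
Run: python examples/04_attenuation.py  (about two minutes)
"""

import numpy as np

import jointglmm as jg

marginals = {
    "x1": {"dist": "bernoulli", "p": 0.5},
    "x2": {"dist": "truncnorm_int", "mean": 0, "sd": 1.5, "low": -4, "high": 4},
}


def fit_all(data):
    fits = {}
    for o in ("cuc", "hiv"):
        fits[f"standard_{o}"] = jg.fit(jg.build_stacked_design(
            data, jg.ModelSpec.standard(o, ("x1", "x2"))))
        fits[f"separate_{o}"] = jg.fit(jg.build_stacked_design(
            data, jg.ModelSpec.separate(o, ("x1", "x2"), order=3)))
    fits["joint"] = jg.fit(jg.build_stacked_design(
        data, jg.ModelSpec.joint(("x1", "x2"), order=3)))
    return fits


for sigma_u, label in ((0.0, "independent outcomes (sigma_u = 0)"),
                       (1.0, "shared woman intercept (sigma_u = 1)")):
    truth = jg.TrueParameters(
        covariates=("x1", "x2"),
        beta_cuc=np.array([0.4, -0.3, 0.5]),
        beta_hiv=np.array([-0.2, 0.4, 0.3]),
        sigma_u=sigma_u)
    config = jg.SimConfig(4, 10, 60, covariate_marginals=marginals, seed=100)
    data = jg.simulate_outcomes(jg.generate_structure(config), truth, seed=101)
    table = jg.compare_joint_separate(fit_all(data))
    print(f"== {label} ==")
    sub = table.loc[:, (slice(None), ["three_level", "joint",
                                      "joint_minus_three_level"], "logodds")]
    print(sub.round(3).to_string())
    print()

print("With sigma_u = 0 the joint and per-outcome estimates coincide up to "
      "noise (differences ~0). With sigma_u = 1 the per-outcome slopes are "
      "attenuated toward zero, so the joint-minus-separate differences are "
      "systematically nonzero — the spillover the joint model recovers.")
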