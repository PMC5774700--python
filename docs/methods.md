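# Methods

## The model

`jointglmm` fits two correlated binary outcomes per woman — current
contraceptive use (CUC, `y_cuc`) and knowledge of HIV/STDs (`y_hiv`) — in a
three-level survey design: women nested in enumeration-area clusters nested
in administrative divisions. Writing `i ∈ {1, 2}` for the outcome, `j` for
the woman, `c(j)` her cluster and `d(j)` her division,

    logit P(y_ij = 1 | x_j, u_j, b_c, b_d) = x_j' β_i + u_j + b_{c(j)} + b_{d(j)}

with independent normal random intercepts

    u_j ~ N(0, σ_u²),   b_c ~ N(0, σ_clu²),   b_d ~ N(0, σ_div²).

Every latent intercept enters **both** outcomes' linear predictors with
loading 1 ("shared random effects"): the woman-level `u_j` induces the
within-woman correlation between CUC and HIV knowledge, and the cluster and
division intercepts induce geographic intra-class correlation. Conditional
on the intercepts, all Bernoulli responses are independent, which gives the
marginal likelihood

    L = Π_d ∫ φ_σdiv(b_d) Π_{c∈d} ∫ φ_σclu(b_c) Π_{j∈c} ∫ φ_σu(u)
          Π_i Bern(y_ij | p_ij) du db_c db_d .

Fixed effects are outcome-specific (β₁ ≠ β₂) with a common covariate set:
the two outcomes are stacked as two rows per woman with exclusive indicator
columns, so a single design matrix carries both coefficient blocks.

Three nested model families share one code path:

* **standard** — no random effects (plain logistic regression per outcome);
* **separate three-level** — one outcome, cluster + division intercepts.
  The woman-level σ_u is deliberately excluded here: with a single Bernoulli
  observation per woman it is unidentifiable;
* **joint** — both outcomes, woman + cluster + division shared intercepts.

Random slopes are supported as an option (one user-named covariate, slope
variance at the cluster and/or division level, independent of the
intercepts) and are off by default; nothing in the motivating study pins
down which covariate would carry the slope.

## Estimation

The integrals have no closed form. Each one-dimensional integral is
replaced by a Gauss–Hermite rule standardized against the standard normal
(Σw = 1, Σw z² = 1; exact for polynomial moments up to degree 2·order−1) and
the sums are carried out innermost-first in log space (women → clusters →
divisions), so the cost is O(orderᴸ) per stacked row for L active levels.

**Adaptive centering.** The raw rule places nodes at σ·z_k, which fails
when a unit's integrand is much narrower than its prior — a division with
hundreds of women has a posterior for b_d that is an order of magnitude
tighter than φ_σdiv. Each level's rule is therefore re-centered at the
unit's posterior mode and rescaled by the posterior curvature (modes from a
blockwise-Newton maximization of the penalized log-likelihood, curvature
from Σ p(1−p) plus the prior precision). The change-of-variables correction
keeps the rule a consistent approximation of the same integral at any
order; adaptivity only accelerates convergence. On the benchmark design
below, doubling the order from the default changes the log-likelihood by
2.7×10⁻⁷ relative (the same check without adaptation moves it by 5×10⁻⁵).
Default order: 11 per level. Random-slope models currently use the
non-adaptive grids.

**Optimization.** The packed parameter vector is (β blocks, log σ per
active component); the log transform keeps standard deviations positive and
unconstrained. L-BFGS-B maximizes the marginal log-likelihood with the
analytic score obtained from the Fisher identity — the gradient of the
marginal log-likelihood equals the posterior expectation of the
complete-data score, computable in the same quadrature pass (for β:
Σ_r x_r (y_r − E[p_r]); for log σ: Σ_units E[v²/σ² − 1]). Log-SDs are
box-bounded in [−10, 5] so a variance shrinking to the boundary cannot
stall the line search. Starting values: per-outcome plain-logistic
coefficients, all σ at 0.1. Convergence: projected-gradient norm 10⁻⁵ or
relative objective change ~10⁻¹¹.

**Uncertainty.** The covariance of the estimates is the inverse of a
numerical observed information: symmetrized central differences (relative
step 10⁻⁴) of the analytic score where available, of the log-likelihood
otherwise. An indefinite Hessian is repaired by eigenvalue clipping and
flagged on the result. Wald odds-ratio tables report OR = exp(β̂),
z = β̂/SE and two-sided normal p-values; variance components are reported
on the variance scale with delta-method SEs and are **tested** separately
(below), not via Wald p-values.

## Diagnostics

* **Hosmer–Lemeshow** calibration chi-square on fitted probabilities of the
  pooled standard logistic fit: sort by p̂, cut into near-equal bins keeping
  ties together, Σ (O−E)²/(E(1−E/n)), df = groups − 2. A bin with fewer
  than half an expected event (or non-event) raises an error suggesting
  fewer groups.
* **Variance-component LRT with boundary correction.** σ = 0 lies on the
  boundary of the parameter space, so 2(ℓ_full − ℓ_reduced) is referred to
  the 50:50 mixture of χ²₀ and χ²₁ (p = ½·P(χ²₁ > stat); p(2.706) = 0.05).
  The simulation study below confirms ~5% size at a true-null design.
* **Empirical-Bayes prediction** of unit effects by sequential conditional
  modes: division modes maximize the exact marginal posterior of b_d (lower
  levels integrated by quadrature); cluster modes condition on the division
  modes; woman modes condition on both (vectorized Newton on a concave 1-D
  posterior). This supports the "which division over-performs" ranking; for
  balanced designs predicted effects average near zero. Intercept models
  only.
* **Joint-vs-separate comparison table** aligning log-odds, OR and p across
  the three families, with an explicit joint-minus-three-level difference
  column. The table is descriptive: when outcomes share latent variance,
  per-outcome fits estimate attenuated marginal slopes while the joint fit
  recovers conditional ones, and the difference column makes that spillover
  visible.

## Synthetic data

The generator emulates the structure of a national demographic survey round
with ~16,000 ever-married women in ~600 clusters across 7 divisions.
Defaults: 7 divisions × 85 clusters × 27 women; covariate marginals equal
to the published sample frequency table (education 27.3/30.3/34.6/7.8%,
wealth quintiles 17.7–23.6%, radio 8.9%, TV 45.7%, Islam 88.5%, urban
35.1%; age, age at first marriage and children as bounded rounded normals
matching the published means/SDs). Outcomes come from the model above with
slopes set to the study's joint-model odds ratios, intercepts calibrated
once by Monte Carlo so the simulated prevalences match the published sample
(59.8% CUC, 70.5% HIV knowledge), σ_clu² = 0.050 and σ_div² = 0.204 (the
reported variance components), and σ_u = 1.0 — the woman-level SD is not
reported anywhere, and 1.0 gives a clear but not extreme within-woman
association (tetrachoric-style excess P₁₁ − P₁·P₂ ≈ 0.05).

What the generator does **not** emulate: probability-proportional-to-size
cluster selection and survey weights (the fitted models are unweighted);
covariate intercorrelations (draws are independent — the published table
reports only marginals); and non-response. Passing tests therefore
demonstrate correctness of the estimator under its own assumptions, not
robustness to the design features of the real survey.

A note on identification: with exactly one binary pair per woman, σ_u is
identified only through the within-woman 2×2 association, so on data
generated with σ_u = 0 its estimate can sit visibly above zero (a chance
residual correlation of ~0.03 at n = 5,000 supports σ̂_u ≈ 0.35). The
cluster and division variances, with dozens of Bernoullis per unit, pin
near zero in the same situation.

## Simulation studies (`jointglmm.studies`)

* **Benchmark recovery**: 10 divisions × 20 clusters × 30 women, β_cuc =
  (0.5, −0.4, 0.8), β_hiv = (−0.3, 0.6, 0.2), σ_u = 1, σ_clu = 0.3,
  σ_div = 0.5; single fit at order 5; every fixed effect lands within 3
  Wald SEs of truth.
* **Coverage**: 50 replicates of the same design at order 4 (fixed-effect
  quadrature bias under a third of an SE at that order); nominal 95% Wald
  intervals and the average of σ̂ per component are checked.
* **LRT null size**: 200 replicates of 12 × 5 × 20 with σ_div = 0,
  intercept + one covariate, order 3; rejection rate at α = 0.05.
* **Independence / attenuation**: 5 × 10 × 100 women with all σ = 0 (joint
  ≈ separate) and with σ_u = 1, where the attenuated per-outcome slope is
  pinned by a brute-force oracle — a plain logistic fit to 400,000 women
  simulated from the same mechanism.

Study sizes and orders are the package's choice of desk-scale designs; they
are documented here precisely so the reported behavior is reproducible with
`scripts/acceptance.py`.

## Numerical choices and degenerate inputs

* Levels excluded from a spec collapse to a single zero node (exact); with
  active levels and σ → 0 the likelihood tends continuously to the
  independent-logistic closed form (σ = 10⁻⁸ agrees to ~10⁻¹⁴).
* A constant outcome (all 0 or all 1) raises a separation error before
  optimization.
* Grouped reductions assume rows sorted division ⊃ cluster ⊃ woman; the
  design builder sorts and validates nesting, so the likelihood is
  invariant under row permutation and relabeling of ids.
* Quadrature nodes are symmetrized so the node set is exactly ±-paired.
* Memory is bounded by processing divisions in chunks of ≤ 4×10⁶
  row-by-node floats.

## Known limitations

* Per-outcome loadings of the shared intercepts are fixed at 1; a
  free-loading variant (one extra parameter per level) is a natural
  extension the current parameterization reserves space for.
* Wald p-values for fixed effects are asymptotic; no profile-likelihood or
  robust (sandwich) intervals.
* Empirical-Bayes predictions are modes, not means, and carry no SEs.
* The Hosmer–Lemeshow test is applied to the pooled standard fit; its use
  as a motivation for multilevel structure is heuristic.
* No survey weights; estimates target the simulated population, not a
  design-weighted one.
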