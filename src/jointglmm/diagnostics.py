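"""Model assessment: calibration, variance-component tests, empirical-Bayes
random-effect prediction, and the joint-vs-separate attenuation comparison.

The variance-component test accounts for the null value sitting on the
boundary of the parameter space: the likelihood-ratio statistic for a single
variance is compared to a 50:50 mixture of a point mass at zero and a
chi-square with one degree of freedom, not to a plain chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import chi2, norm

from .design import ModelParams, StackedDesign, fixed_predictor
from .estimation import (
    FitResult,
    QuadratureRule,
    _cluster_block,
    _division_block,
    _grids,
    gauss_hermite_rule,
)

__all__ = [
    "HLResult",
    "hosmer_lemeshow",
    "LRTResult",
    "lrt_variance_component",
    "mixture_pvalue",
    "RandomEffectPredictions",
    "predict_random_effects",
    "compare_joint_separate",
]


# --------------------------------------------------------------------------
# Hosmer-Lemeshow calibration test
# --------------------------------------------------------------------------

@dataclass
class HLResult:
    groups: int
    statistic: float
    df: int
    p: float
    table: pd.DataFrame


def hosmer_lemeshow(y, phat, groups: int = 10) -> HLResult:
    """Calibration chi-square over near-equal-size bins of sorted fitted
    probabilities (ties on phat stay in one bin).

    statistic = sum_g (O_g - E_g)^2 / (E_g (1 - E_g / n_g)), df = G - 2.
    """
    y = np.asarray(y, dtype=float)
    phat = np.asarray(phat, dtype=float)
    if y.shape != phat.shape:
        raise ValueError("y and phat must have equal length")
    if (phat <= 0).any() or (phat >= 1).any():
        raise ValueError("phat must lie strictly inside (0, 1)")
    n = len(y)
    order = np.argsort(phat, kind="mergesort")
    ys, ps = y[order], phat[order]

    edges = [0]
    for g in range(1, groups):
        e = round(g * n / groups)
        while 0 < e < n and ps[e] == ps[e - 1]:
            e += 1
        if e > edges[-1] and e < n:
            edges.append(e)
    edges.append(n)

    rows = []
    stat = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        ng = hi - lo
        O = ys[lo:hi].sum()
        E = ps[lo:hi].sum()
        # fewer than half an expected event (or non-event) in a bin makes the
        # chi-square denominator meaningless
        if E <= 0.5 or E >= ng - 0.5:
            raise ValueError(
                "a bin has (near-)degenerate expected count; use fewer groups"
            )
        stat += (O - E) ** 2 / (E * (1.0 - E / ng))
        rows.append({"phat_low": ps[lo], "phat_high": ps[hi - 1], "n": ng,
                     "observed": O, "expected": E})
    table = pd.DataFrame(rows)
    G = len(rows)
    df = G - 2
    if df >= 1:
        p = float(chi2.sf(stat, df))
    else:
        p = 1.0 if stat < 1e-12 else float("nan")
    return HLResult(groups=G, statistic=float(stat), df=df, p=p, table=table)


# --------------------------------------------------------------------------
# boundary likelihood-ratio test for one variance component
# --------------------------------------------------------------------------

@dataclass
class LRTResult:
    component: str
    statistic: float
    p: float


def mixture_pvalue(stat: float) -> float:
    """Tail probability of the 50:50 chi2_0 : chi2_1 boundary mixture."""
    if stat <= 0:
        return 1.0
    return float(0.5 * chi2.sf(stat, 1))


def lrt_variance_component(fit_full: FitResult, fit_reduced: FitResult) -> LRTResult:
    """LRT of a single variance component against zero, with the boundary
    mixture null; the reduced fit must drop exactly one random-effect level
    of the full fit on the same data and covariates."""
    sf, sr = fit_full.spec, fit_reduced.spec
    if sf.outcomes != sr.outcomes or sf.covariates != sr.covariates \
            or sf.random_slope != sr.random_slope:
        raise ValueError("fits are not nested: outcomes/covariates differ")
    dropped = set(sf.levels) - set(sr.levels)
    if len(dropped) != 1 or not set(sr.levels) <= set(sf.levels):
        raise ValueError(
            "reduced spec must equal the full spec with exactly one "
            f"random-effect level removed (got full={sf.levels}, "
            f"reduced={sr.levels})"
        )
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    return LRTResult(component=dropped.pop(), statistic=stat, p=mixture_pvalue(stat))


# --------------------------------------------------------------------------
# empirical-Bayes random-effect prediction
# --------------------------------------------------------------------------

@dataclass
class RandomEffectPredictions:
    division: pd.Series
    cluster: pd.Series
    woman: pd.Series

    def ranked_divisions(self) -> pd.Series:
        """Divisions ordered by predicted effect, largest first."""
        return self.division.sort_values(ascending=False)


_SIGMA_TINY = 1e-8


def predict_random_effects(fit_result: FitResult | ModelParams,
                           design: StackedDesign,
                           rule: QuadratureRule | None = None,
                           xatol: float = 1e-9) -> RandomEffectPredictions:
    """Posterior modes of the random effects given data and estimates.

    Division modes maximize the marginal posterior of the division intercept
    with cluster and woman effects integrated out by quadrature; cluster
    modes condition on the division modes; woman modes condition on both
    (closed-form Newton iterations). A level whose estimated SD is zero (or
    which the spec excludes) gets all-zero predictions.
    """
    params = fit_result.params if isinstance(fit_result, FitResult) else fit_result
    spec = design.spec
    if spec.random_slope is not None:
        raise NotImplementedError("random-effect prediction: intercept models only")
    rule = rule or gauss_hermite_rule(spec.quadrature_order)
    eta0 = fixed_predictor(design, params)
    _, cl, wm = _grids(design, params, rule)

    sd_div = params.sigma_div if "division" in spec.levels else 0.0
    sd_clu = params.sigma_clu if "cluster" in spec.levels else 0.0
    sd_u = params.sigma_u if "individual" in spec.levels else 0.0

    b_div = np.zeros(design.n_divisions)
    if sd_div > _SIGMA_TINY:
        for d in range(design.n_divisions):
            def nld(b, d=d):
                lp = norm.logpdf(b, 0.0, sd_div)
                return -(lp + _division_block(design, eta0, cl, wm, d,
                                              np.array([b]), None)[0])
            res = minimize_scalar(nld, bounds=(-6 * sd_div, 6 * sd_div),
                                  method="bounded", options={"xatol": xatol})
            b_div[d] = res.x

    b_clu = np.zeros(design.n_clusters)
    if sd_clu > _SIGMA_TINY:
        for c in range(design.n_clusters):
            off = b_div[design.division_of_cluster[c]]
            def nlc(b, c=c, off=off):
                lp = norm.logpdf(b, 0.0, sd_clu)
                return -(lp + _cluster_block(design, eta0, wm, c,
                                             np.array([off + b]))[0])
            res = minimize_scalar(nlc, bounds=(-6 * sd_clu, 6 * sd_clu),
                                  method="bounded", options={"xatol": xatol})
            b_clu[c] = res.x

    u = np.zeros(design.n_women)
    if sd_u > _SIGMA_TINY:
        n_out = spec.n_outcomes
        eta0w = eta0.reshape(design.n_women, n_out)
        yw = design.y.reshape(design.n_women, n_out).astype(float)
        offset = (b_div[design.division_of_cluster[design.cluster_of_woman]]
                  + b_clu[design.cluster_of_woman])
        for _ in range(100):
            p = expit(eta0w + (offset + u)[:, None])
            g = -u / sd_u ** 2 + (yw - p).sum(axis=1)
            h = -1.0 / sd_u ** 2 - (p * (1.0 - p)).sum(axis=1)
            step = g / h
            u -= step
            if np.max(np.abs(step)) < 1e-12:
                break

    return RandomEffectPredictions(
        division=pd.Series(b_div, index=design.division_labels, name="division_effect"),
        cluster=pd.Series(b_clu, index=design.cluster_labels, name="cluster_effect"),
        woman=pd.Series(u, index=design.woman_labels, name="woman_effect"),
    )


# --------------------------------------------------------------------------
# joint vs separate comparison (attenuation / spillover table)
# --------------------------------------------------------------------------

_REQUIRED_FITS = ("standard_cuc", "standard_hiv", "separate_cuc",
                  "separate_hiv", "joint")


def compare_joint_separate(fits: Mapping[str, FitResult]) -> pd.DataFrame:
    """Align log-odds, OR and p across the three model families.

    Rows are coefficients (Intercept first), columns a MultiIndex
    (outcome, model, metric) with models ``standard``, ``three_level`` and
    ``joint``, plus a ``joint_minus_three_level`` log-odds difference per
    outcome. Purely descriptive: the table quantifies how much covariate
    effects move once the within-woman outcome correlation is modeled.
    """
    missing = [k for k in _REQUIRED_FITS if k not in fits]
    if missing:
        raise ValueError(f"missing fit(s): {', '.join(missing)}")
    covs = {k: f.spec.covariates for k, f in fits.items()}
    if len(set(covs.values())) != 1:
        raise ValueError(f"fits use different covariate sets: {covs}")

    names = list(fits["joint"].or_table.query("outcome == 'cuc'")["name"])
    cols = {}
    for outcome in ("cuc", "hiv"):
        per_model = {}
        for model, key in (("standard", f"standard_{outcome}"),
                           ("three_level", f"separate_{outcome}"),
                           ("joint", "joint")):
            t = fits[key].or_table
            t = t[t["outcome"] == outcome].set_index("name")
            per_model[model] = t
            for metric in ("logodds", "OR", "p"):
                cols[(outcome, model, metric)] = t.loc[names, metric].to_numpy()
        cols[(outcome, "joint_minus_three_level", "logodds")] = (
            cols[(outcome, "joint", "logodds")]
            - cols[(outcome, "three_level", "logodds")]
        )
    table = pd.DataFrame(cols, index=pd.Index(names, name="coefficient"))
    table.columns = pd.MultiIndex.from_tuples(
        table.columns, names=["outcome", "model", "metric"])
    return table
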