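"""Maximum-likelihood estimation of the shared-random-intercept joint model.

The marginal log-likelihood integrates the normal random intercepts out of
the conditional Bernoulli likelihood:

    l = sum_d log Int phi(b_d) prod_{c in d} Int phi(b_c)
            prod_{j in c} Int phi(u_j) prod_i Bern(y_ij | p_ij) du db_c db_d

with logit p_ij = x_j' beta_i + b_d + b_c + u_j. Each one-dimensional
integral is replaced by a Gauss-Hermite rule standardized against the
standard-normal density and scaled by that level's standard deviation; the
sums are carried out innermost-first (women, then clusters, then divisions)
in log space, so the cost is O(order^L) per row for L active levels.

Three model families share this code path: "standard" (no random effects,
the integrals collapse), per-outcome three-level models (cluster + division
intercepts), and the joint model (woman + cluster + division shared
intercepts across both outcomes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .design import (
    DISPLAY_NAMES,
    Layout,
    ModelParams,
    ModelSpec,
    StackedDesign,
    fixed_predictor,
)

__all__ = [
    "QuadratureRule",
    "gauss_hermite_rule",
    "conditional_loglik_woman",
    "marginal_loglik",
    "fit",
    "FitResult",
    "observed_information",
    "numerical_hessian",
    "odds_ratio_table",
    "SeparationError",
    "ConvergenceWarning",
]


class SeparationError(ValueError):
    """An outcome is constant (all 0 or all 1); the MLE does not exist."""


class ConvergenceWarning(UserWarning):
    pass


# --------------------------------------------------------------------------
# quadrature
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadratureRule:
    """Gauss-Hermite nodes/weights standardized so that sum w_k f(z_k)
    approximates E[f(Z)] for Z ~ N(0, 1); exact for polynomials up to
    degree 2*order - 1."""

    order: int
    nodes: np.ndarray
    weights: np.ndarray


def gauss_hermite_rule(order: int) -> QuadratureRule:
    if order < 1:
        raise ValueError("quadrature order must be >= 1")
    x, w = np.polynomial.hermite.hermgauss(order)
    z = x * np.sqrt(2.0)
    wt = w / np.sqrt(np.pi)
    # enforce exact +- symmetry of the node set
    z = 0.5 * (z - z[::-1])
    wt = 0.5 * (wt + wt[::-1])
    return QuadratureRule(order=order, nodes=z, weights=wt)


class _LevelGrid(NamedTuple):
    """Node values and log-weights for one random-effect level.

    ``vals``/``logw`` have shape (n_units, K) when the grid is adapted per
    unit, or (1, K) when the same grid serves every unit; ``slp`` holds slope
    coefficients (to be multiplied by the row's slope covariate) or None. An
    inactive level is a single zero node with log-weight 0, a no-op."""

    vals: np.ndarray
    logw: np.ndarray
    slp: np.ndarray | None


def _level_grid(rule: QuadratureRule, sigma_int: float, has_int: bool,
                sigma_slp: float = 0.0, has_slp: bool = False) -> _LevelGrid:
    """Non-adaptive grid: nodes at sigma * z_k, prior folded into weights."""
    logw1 = np.log(rule.weights)
    if not has_int and not has_slp:
        return _LevelGrid(np.zeros((1, 1)), np.zeros((1, 1)), None)
    if has_int and not has_slp:
        return _LevelGrid(sigma_int * rule.nodes[None, :], logw1[None, :], None)
    if has_slp and not has_int:
        return _LevelGrid(np.zeros((1, rule.order)), logw1[None, :],
                          sigma_slp * rule.nodes)
    K = rule.order
    return _LevelGrid(
        np.repeat(sigma_int * rule.nodes, K)[None, :],
        (logw1[:, None] + logw1[None, :]).ravel()[None, :],
        np.tile(sigma_slp * rule.nodes, K),
    )


def _grids(design: StackedDesign, params: ModelParams,
           rule: QuadratureRule) -> tuple[_LevelGrid, _LevelGrid, _LevelGrid]:
    spec = design.spec
    slope = spec.random_slope is not None
    dv = _level_grid(rule, params.sigma_div, "division" in spec.levels,
                     params.sigma_slope_div, slope and "division" in spec.slope_levels)
    cl = _level_grid(rule, params.sigma_clu, "cluster" in spec.levels,
                     params.sigma_slope_clu, slope and "cluster" in spec.slope_levels)
    wm = _level_grid(rule, params.sigma_u, "individual" in spec.levels)
    return dv, cl, wm


_TINY_SIGMA = 1e-12


def _conditional_modes(design: StackedDesign, params: ModelParams,
                       eta0: np.ndarray, n_iter: int = 80,
                       tol: float = 1e-10):
    """Joint posterior modes of all random intercepts given the parameters,
    by blockwise Newton ascent (the penalized log-likelihood is concave), and
    the curvature weights sum_i p(1-p) per unit at the modes."""
    spec = design.spec
    yf = design.y.astype(float)
    woman_row = design.woman_of_row
    clu_row = design.cluster_of_woman[woman_row]
    div_row = design.division_of_cluster[clu_row]

    act_u = "individual" in spec.levels and params.sigma_u > _TINY_SIGMA
    act_c = "cluster" in spec.levels and params.sigma_clu > _TINY_SIGMA
    act_d = "division" in spec.levels and params.sigma_div > _TINY_SIGMA
    u = np.zeros(design.n_women)
    bc = np.zeros(design.n_clusters)
    bd = np.zeros(design.n_divisions)

    def eta():
        e = eta0
        if act_d:
            e = e + bd[div_row]
        if act_c:
            e = e + bc[clu_row]
        if act_u:
            e = e + u[woman_row]
        return e

    updates = []
    if act_u:
        updates.append((u, woman_row, design.n_women, params.sigma_u))
    if act_c:
        updates.append((bc, clu_row, design.n_clusters, params.sigma_clu))
    if act_d:
        updates.append((bd, div_row, design.n_divisions, params.sigma_div))

    for _ in range(n_iter):
        worst = 0.0
        for vec, rows, n_units, sigma in updates:
            p = expit(eta())
            g = np.bincount(rows, yf - p, minlength=n_units) - vec / sigma ** 2
            h = np.bincount(rows, p * (1.0 - p), minlength=n_units) + 1.0 / sigma ** 2
            step = g / h
            vec += step
            worst = max(worst, float(np.max(np.abs(step))))
        if worst < tol:
            break

    w = expit(eta())
    w = w * (1.0 - w)
    W_u = np.bincount(woman_row, w, minlength=design.n_women) if act_u else None
    W_c = np.bincount(clu_row, w, minlength=design.n_clusters) if act_c else None
    W_d = np.bincount(div_row, w, minlength=design.n_divisions) if act_d else None
    return (u if act_u else None, W_u), (bc if act_c else None, W_c), \
        (bd if act_d else None, W_d)


def _adaptive_level(rule: QuadratureRule, sigma: float, mode: np.ndarray | None,
                    W: np.ndarray | None) -> _LevelGrid:
    """Grid re-centered at each unit's posterior mode and rescaled by the
    posterior curvature; the change-of-variables correction keeps the rule a
    consistent approximation of the same integral at any order."""
    if mode is None:
        return _LevelGrid(np.zeros((1, 1)), np.zeros((1, 1)), None)
    z, w1 = rule.nodes, rule.weights
    s = 1.0 / np.sqrt(1.0 / sigma ** 2 + W)
    vals = mode[:, None] + s[:, None] * z[None, :]
    logw = (norm.logpdf(vals, 0.0, sigma) + np.log(s)[:, None]
            + np.log(w1)[None, :] + 0.5 * z[None, :] ** 2
            + 0.5 * np.log(2.0 * np.pi))
    return _LevelGrid(vals, logw, None)


def _adaptive_grids(design: StackedDesign, params: ModelParams,
                    rule: QuadratureRule, eta0: np.ndarray):
    (m_u, W_u), (m_c, W_c), (m_d, W_d) = _conditional_modes(design, params, eta0)
    wm = _adaptive_level(rule, params.sigma_u, m_u, W_u)
    cl = _adaptive_level(rule, params.sigma_clu, m_c, W_c)
    dv = _adaptive_level(rule, params.sigma_div, m_d, W_d)
    return dv, cl, wm


# --------------------------------------------------------------------------
# likelihood
# --------------------------------------------------------------------------

def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Elementwise y*log p + (1-y)*log(1-p), computed underflow-safely."""
    s = 2.0 * np.asarray(y, dtype=float) - 1.0
    return -np.logaddexp(0.0, -s * eta)


def conditional_loglik_woman(design: StackedDesign, woman: int,
                             params: ModelParams, b_div: float, b_clu: float,
                             u: float) -> float:
    """Log-likelihood of one woman's outcome rows given realized effects.

    Conditional on the shared intercepts, her two responses are independent
    Bernoulli variables, so this is a plain sum over her rows."""
    if design.spec.random_slope is not None:
        raise NotImplementedError("conditional_loglik_woman: intercept models only")
    r0, r1 = design.woman_row_starts[woman], design.woman_row_starts[woman + 1]
    eta0 = fixed_predictor(design, params)[r0:r1]
    return float(bernoulli_loglik(design.y[r0:r1], eta0 + b_div + b_clu + u).sum())


def _division_block(design: StackedDesign, eta0: np.ndarray,
                    cl: _LevelGrid, wm: _LevelGrid, d: int,
                    div_vals: np.ndarray,
                    div_slp: np.ndarray | None = None) -> np.ndarray:
    """log f_d evaluated at each division offset in ``div_vals``: the cluster
    and woman effects of division d integrated out by quadrature (the
    division-level prior/weights are NOT applied here)."""
    c0, c1 = design.division_cluster_starts[d], design.division_cluster_starts[d + 1]
    w0, w1 = design.cluster_woman_starts[c0], design.cluster_woman_starts[c1]
    r0, r1 = design.woman_row_starts[w0], design.woman_row_starts[w1]

    z = design.slope_z[r0:r1] if design.slope_z is not None else None
    Cd = div_vals[None, :] if div_slp is None \
        else div_vals[None, :] + np.outer(z, div_slp)

    if cl.vals.shape[0] == 1:
        Cc = cl.vals if cl.slp is None else cl.vals + np.outer(z, cl.slp)
        logw_c = cl.logw                              # (1, KC)
    else:
        crow = design.cluster_of_woman[design.woman_of_row[r0:r1]]
        Cc = cl.vals[crow]                            # (nr, KC)
        logw_c = cl.logw[c0:c1]                       # (nc, KC)

    if wm.vals.shape[0] == 1:
        Cu = wm.vals
        logw_u = wm.logw                              # (1, KU)
    else:
        Cu = wm.vals[design.woman_of_row[r0:r1]]      # (nr, KU)
        logw_u = wm.logw[w0:w1]                       # (nw, KU)

    s = 2.0 * design.y[r0:r1].astype(float) - 1.0
    eta = (eta0[r0:r1, None, None, None]
           + Cd[:, :, None, None] + Cc[:, None, :, None] + Cu[:, None, None, :])
    ll = -np.logaddexp(0.0, -s[:, None, None, None] * eta)

    wsum = np.add.reduceat(ll, design.woman_row_starts[w0:w1] - r0, axis=0)
    g = logsumexp(wsum + logw_u[:, None, None, :], axis=3)   # (nw, KD, KC)
    csum = np.add.reduceat(g, design.cluster_woman_starts[c0:c1] - w0, axis=0)
    h = logsumexp(csum + logw_c[:, None, :], axis=2)         # (nc, KD)
    out = h.sum(axis=0)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            f"non-finite marginal likelihood contribution in division "
            f"{design.division_labels[d]!r}"
        )
    return out


def _cluster_block(design: StackedDesign, eta0: np.ndarray, wm: _LevelGrid,
                   c: int, t_vals: np.ndarray) -> np.ndarray:
    """sum_j log g_j(t) over the women of cluster c, where t is the combined
    division + cluster offset and the woman effect is integrated out."""
    w0, w1 = design.cluster_woman_starts[c], design.cluster_woman_starts[c + 1]
    r0, r1 = design.woman_row_starts[w0], design.woman_row_starts[w1]
    Cu = wm.vals if wm.vals.shape[0] == 1 else wm.vals[design.woman_of_row[r0:r1]]
    logw_u = wm.logw if wm.logw.shape[0] == 1 else wm.logw[w0:w1]
    s = 2.0 * design.y[r0:r1].astype(float) - 1.0
    eta = eta0[r0:r1, None, None] + t_vals[None, :, None] + Cu[:, None, :]
    ll = -np.logaddexp(0.0, -s[:, None, None] * eta)
    wsum = np.add.reduceat(ll, design.woman_row_starts[w0:w1] - r0, axis=0)
    g = logsumexp(wsum + logw_u[:, None, :], axis=2)         # (n_women_c, T)
    return g.sum(axis=0)


def _chunk_loglik(design: StackedDesign, eta0: np.ndarray, dv: _LevelGrid,
                  cl: _LevelGrid, wm: _LevelGrid, d0: int, d1: int) -> float:
    """Summed log-likelihood of divisions [d0, d1) in one staged reduction."""
    c0, c1 = design.division_cluster_starts[d0], design.division_cluster_starts[d1]
    w0, w1 = design.cluster_woman_starts[c0], design.cluster_woman_starts[c1]
    r0, r1 = design.woman_row_starts[w0], design.woman_row_starts[w1]

    z = design.slope_z[r0:r1] if design.slope_z is not None else None
    wrow = design.woman_of_row[r0:r1]
    crow = design.cluster_of_woman[wrow]

    if dv.vals.shape[0] == 1:
        Cd = dv.vals if dv.slp is None else dv.vals + np.outer(z, dv.slp)
        logw_d = dv.logw                              # (1, KD)
    else:
        Cd = dv.vals[design.division_of_cluster[crow]]
        logw_d = dv.logw[d0:d1]                       # (nd, KD)

    if cl.vals.shape[0] == 1:
        Cc = cl.vals if cl.slp is None else cl.vals + np.outer(z, cl.slp)
        logw_c = cl.logw                              # (1, KC)
    else:
        Cc = cl.vals[crow]                            # (nr, KC)
        logw_c = cl.logw[c0:c1]                       # (nc, KC)

    if wm.vals.shape[0] == 1:
        Cu = wm.vals
        logw_u = wm.logw                              # (1, KU)
    else:
        Cu = wm.vals[wrow]                            # (nr, KU)
        logw_u = wm.logw[w0:w1]                       # (nw, KU)

    s = 2.0 * design.y[r0:r1].astype(float) - 1.0
    eta = (eta0[r0:r1, None, None, None]
           + Cd[:, :, None, None] + Cc[:, None, :, None] + Cu[:, None, None, :])
    ll = -np.logaddexp(0.0, -s[:, None, None, None] * eta)

    wsum = np.add.reduceat(ll, design.woman_row_starts[w0:w1] - r0, axis=0)
    g = logsumexp(wsum + logw_u[:, None, None, :], axis=3)   # (nw, KD, KC)
    csum = np.add.reduceat(g, design.cluster_woman_starts[c0:c1] - w0, axis=0)
    h = logsumexp(csum + logw_c[:, None, :], axis=2)         # (nc, KD)
    dsum = np.add.reduceat(h, design.division_cluster_starts[d0:d1] - c0, axis=0)
    per_div = logsumexp(dsum + logw_d, axis=1)               # (nd,)
    if not np.all(np.isfinite(per_div)):
        bad = d0 + int(np.flatnonzero(~np.isfinite(per_div))[0])
        raise FloatingPointError(
            f"non-finite marginal likelihood contribution in division "
            f"{design.division_labels[bad]!r}"
        )
    return float(per_div.sum())


def _chunk_loglik_grad(design: StackedDesign, eta0: np.ndarray,
                       dv: _LevelGrid, cl: _LevelGrid, wm: _LevelGrid,
                       d0: int, d1: int, params: ModelParams,
                       g_beta: np.ndarray, g_sigma: dict) -> float:
    """Like _chunk_loglik, but also accumulates the score of the marginal
    log-likelihood via the Fisher identity: the gradient equals the posterior
    expectation (under the same quadrature) of the complete-data score.

    For the fixed effects that expectation is sum_r x_r (y_r - E[p_r]); for
    log sigma at a level it is sum_units E[v^2/sigma^2 - 1], with v the node
    values actually used. Intercept-only models (no random slopes)."""
    c0, c1 = design.division_cluster_starts[d0], design.division_cluster_starts[d1]
    w0, w1 = design.cluster_woman_starts[c0], design.cluster_woman_starts[c1]
    r0, r1 = design.woman_row_starts[w0], design.woman_row_starts[w1]

    wrow = design.woman_of_row[r0:r1]
    crow = design.cluster_of_woman[wrow]
    drow = design.division_of_cluster[crow]

    def vals_logw(grid, unit_lo, unit_hi):
        if grid.vals.shape[0] == 1:
            return grid.vals, grid.logw
        return grid.vals[unit_lo:unit_hi], grid.logw[unit_lo:unit_hi]

    dvals, dlogw = vals_logw(dv, d0, d1)
    cvals, clogw = vals_logw(cl, c0, c1)
    uvals, ulogw = vals_logw(wm, w0, w1)
    Cd = dvals if dv.vals.shape[0] == 1 else dv.vals[drow]
    Cc = cvals if cl.vals.shape[0] == 1 else cl.vals[crow]
    Cu = uvals if wm.vals.shape[0] == 1 else wm.vals[wrow]

    s = 2.0 * design.y[r0:r1].astype(float) - 1.0
    eta = (eta0[r0:r1, None, None, None]
           + Cd[:, :, None, None] + Cc[:, None, :, None] + Cu[:, None, None, :])
    ll = -np.logaddexp(0.0, -s[:, None, None, None] * eta)

    wsum = np.add.reduceat(ll, design.woman_row_starts[w0:w1] - r0, axis=0)
    del ll
    g = logsumexp(wsum + ulogw[:, None, None, :], axis=3)
    csum = np.add.reduceat(g, design.cluster_woman_starts[c0:c1] - w0, axis=0)
    h = logsumexp(csum + clogw[:, None, :], axis=2)
    dsum = np.add.reduceat(h, design.division_cluster_starts[d0:d1] - c0, axis=0)
    per_div = logsumexp(dsum + dlogw, axis=1)
    if not np.all(np.isfinite(per_div)):
        bad = d0 + int(np.flatnonzero(~np.isfinite(per_div))[0])
        raise FloatingPointError(
            f"non-finite marginal likelihood contribution in division "
            f"{design.division_labels[bad]!r}"
        )

    # posterior weights, conditional level by level
    PD = np.exp(dsum + dlogw - per_div[:, None])                 # (nd, KD)
    PC = np.exp(csum + clogw[:, None, :] - h[:, :, None])        # (nc, KD, KC)
    PU = np.exp(wsum + ulogw[:, None, None, :] - g[..., None])   # (nw, KD, KC, KU)

    p = expit(eta)
    del eta
    wl, cll, dl = wrow - w0, crow - c0, drow - d0
    A = (PU[wl] * p).sum(axis=3)                                 # (nr, KD, KC)
    del p
    B = (PC[cll] * A).sum(axis=2)                                # (nr, KD)
    pbar = (PD[dl] * B).sum(axis=1)                              # (nr,)
    resid = design.y[r0:r1] - pbar

    p1 = design.X.shape[1]
    for k in range(design.spec.n_outcomes):
        m = design.outcome_idx[r0:r1] == k
        g_beta[k * p1:(k + 1) * p1] += design.X[r0:r1][m].T @ resid[m]

    spec = design.spec
    if "sigma_u" in g_sigma:
        w_of = design.cluster_of_woman[w0:w1]
        d_of_w = design.division_of_cluster[w_of] - d0
        c_of_w = w_of - c0
        Mab = (PC[c_of_w][..., None] * PU).sum(axis=2)           # (nw, KD, KU)
        Mk = (PD[d_of_w][:, :, None] * Mab).sum(axis=1)          # (nw, KU)
        g_sigma["sigma_u"] += float(
            (Mk * (uvals ** 2 / params.sigma_u ** 2 - 1.0)).sum())
    if "sigma_clu" in g_sigma:
        d_of_c = design.division_of_cluster[c0:c1] - d0
        Qc = (PD[d_of_c][:, :, None] * PC).sum(axis=1)           # (nc, KC)
        g_sigma["sigma_clu"] += float(
            (Qc * (cvals ** 2 / params.sigma_clu ** 2 - 1.0)).sum())
    if "sigma_div" in g_sigma:
        g_sigma["sigma_div"] += float(
            (PD * (dvals ** 2 / params.sigma_div ** 2 - 1.0)).sum())
    return float(per_div.sum())


_CHUNK_BUDGET = 4_000_000  # floats in the (rows x KD x KC x KU) block


def _division_chunks(design: StackedDesign, K3: int):
    rows_per_chunk = max(1, _CHUNK_BUDGET // K3)
    d0 = 0
    while d0 < design.n_divisions:
        d1 = d0 + 1
        while d1 < design.n_divisions:
            c_end = design.division_cluster_starts[d1 + 1]
            w_end = design.cluster_woman_starts[c_end]
            r_start = design.woman_row_starts[
                design.cluster_woman_starts[design.division_cluster_starts[d0]]]
            if design.woman_row_starts[w_end] - r_start > rows_per_chunk:
                break
            d1 += 1
        yield d0, d1
        d0 = d1


def marginal_loglik_and_grad(design: StackedDesign, params: ModelParams,
                             rule: QuadratureRule | None = None,
                             adaptive: bool = True
                             ) -> tuple[float, np.ndarray]:
    """Marginal log-likelihood and its gradient with respect to the packed
    (beta, log sigma) parameters, in one quadrature pass (Fisher identity).

    Not available for random-slope models; ``fit`` falls back to finite
    differences there."""
    if design.spec.random_slope is not None:
        raise NotImplementedError("analytic score: intercept models only")
    if rule is None:
        rule = gauss_hermite_rule(design.spec.quadrature_order)
    eta0 = fixed_predictor(design, params)
    if adaptive and design.spec.levels:
        dv, cl, wm = _adaptive_grids(design, params, rule, eta0)
    else:
        dv, cl, wm = _grids(design, params, rule)

    layout_sigmas = design.spec.active_sigmas()
    g_beta = np.zeros(design.spec.n_outcomes * design.X.shape[1])
    g_sigma = {name: 0.0 for name in layout_sigmas}
    K3 = dv.vals.shape[1] * cl.vals.shape[1] * wm.vals.shape[1]
    total = 0.0
    for d0, d1 in _division_chunks(design, K3):
        total += _chunk_loglik_grad(design, eta0, dv, cl, wm, d0, d1,
                                    params, g_beta, g_sigma)
    grad = np.concatenate([g_beta, [g_sigma[n] for n in layout_sigmas]])
    return total, grad


def marginal_loglik(design: StackedDesign, params: ModelParams,
                    rule: QuadratureRule | None = None,
                    adaptive: bool = True) -> float:
    """Marginal log-likelihood with all active random effects integrated out
    by nested Gauss-Hermite quadrature (levels not in the spec collapse to a
    single zero node).

    By default each level's rule is re-centered at the unit's posterior mode
    and rescaled by the posterior curvature (adaptive quadrature); this is a
    change of variables, so any centering converges to the same integral as
    the order grows, but the adaptive version resolves the sharply peaked
    integrands that arise when a cluster or division holds many women. Models
    with random slopes fall back to the non-adaptive grids.
    """
    if rule is None:
        rule = gauss_hermite_rule(design.spec.quadrature_order)
    eta0 = fixed_predictor(design, params)
    if adaptive and design.spec.random_slope is None and design.spec.levels:
        dv, cl, wm = _adaptive_grids(design, params, rule, eta0)
    else:
        dv, cl, wm = _grids(design, params, rule)

    K3 = dv.vals.shape[1] * cl.vals.shape[1] * wm.vals.shape[1]
    total = 0.0
    for d0, d1 in _division_chunks(design, K3):
        total += _chunk_loglik(design, eta0, dv, cl, wm, d0, d1)
    return total


# --------------------------------------------------------------------------
# numerical derivatives
# --------------------------------------------------------------------------

def numerical_hessian(f: Callable[[np.ndarray], float], x: np.ndarray,
                      rel_step: float = 1e-4) -> np.ndarray:
    """Symmetrized central-difference Hessian; exact for quadratics up to
    rounding. Step per coordinate is rel_step * max(|x_i|, 1)."""
    x = np.asarray(x, dtype=float)
    p = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    f0 = f(x)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        e = np.zeros(p); e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
    H = np.empty((p, p))
    np.fill_diagonal(H, (fp - 2.0 * f0 + fm) / h ** 2)
    for i in range(p):
        for j in range(i + 1, p):
            e = np.zeros(p); e[i] = h[i]; e[j] = h[j]
            fpp = f(x + e)
            fmm = f(x - e)
            e[j] = -h[j]
            fpm = f(x + e)
            fmp = f(x - e)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def observed_information(design: StackedDesign, estimates,
                         rule: QuadratureRule | None = None,
                         layout: Layout | None = None,
                         rel_step: float = 1e-4) -> np.ndarray:
    """Numerical Hessian of -marginal_loglik at the estimates, on the packed
    (beta, log sigma) scale."""
    layout = layout or Layout.from_spec(design.spec)
    theta = layout.pack(estimates) if isinstance(estimates, ModelParams) \
        else np.asarray(estimates, dtype=float)
    rule = rule or gauss_hermite_rule(design.spec.quadrature_order)

    if design.spec.random_slope is None:
        # central differences of the analytic score: 2p gradient passes
        p = len(theta)
        h = rel_step * np.maximum(np.abs(theta), 1.0)
        H = np.empty((p, p))
        for i in range(p):
            e = np.zeros(p); e[i] = h[i]
            _, gp = marginal_loglik_and_grad(design, layout.unpack(theta + e), rule)
            _, gm = marginal_loglik_and_grad(design, layout.unpack(theta - e), rule)
            H[i] = -(gp - gm) / (2.0 * h[i])
        return 0.5 * (H + H.T)

    def f(t):
        return -marginal_loglik(design, layout.unpack(t), rule)

    H = numerical_hessian(f, theta, rel_step=rel_step)
    return 0.5 * (H + H.T)


def _safe_inverse(H: np.ndarray) -> tuple[np.ndarray, bool]:
    """Inverse of a should-be-PSD information matrix; repairs by eigenvalue
    clipping when the numerical Hessian is indefinite."""
    try:
        L = np.linalg.cholesky(H)
        inv_l = np.linalg.inv(L)
        return inv_l.T @ inv_l, False
    except np.linalg.LinAlgError:
        evals, evecs = np.linalg.eigh(H)
        floor = max(evals.max(), 1.0) * 1e-10
        clipped = np.maximum(evals, floor)
        warnings.warn("observed information not positive definite; "
                      "eigenvalues clipped", ConvergenceWarning)
        return (evecs / clipped) @ evecs.T, True


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, uncertainty and derived tables for one fitted model."""

    spec: ModelSpec
    params: ModelParams
    theta: np.ndarray
    loglik: float
    cov: np.ndarray | None
    converged: bool
    n_iter: int
    n_evals: int
    grad_norm: float
    or_table: pd.DataFrame
    variance_table: pd.DataFrame
    psd_repaired: bool = False
    layout: Layout = field(default=None, repr=False)

    def beta_se(self) -> np.ndarray | None:
        """Standard errors of the fixed effects, shaped like params.beta."""
        if self.cov is None:
            return None
        nb = self.layout.n_beta
        se = np.sqrt(np.maximum(np.diag(self.cov)[:nb], 0.0))
        return se.reshape(self.params.beta.shape)

    def to_json(self) -> dict:
        s = self.spec
        return {
            "spec": {
                "outcomes": s.outcomes, "covariates": list(s.covariates),
                "levels": list(s.levels), "random_slope": s.random_slope,
                "slope_levels": list(s.slope_levels),
                "quadrature_order": s.quadrature_order,
            },
            "theta": self.theta.tolist(),
            "loglik": self.loglik,
            "cov": None if self.cov is None else self.cov.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_evals": self.n_evals,
            "grad_norm": self.grad_norm,
            "psd_repaired": self.psd_repaired,
            "or_table": self.or_table.to_dict(orient="list"),
            "variance_table": self.variance_table.to_dict(orient="list"),
        }

    @classmethod
    def from_json(cls, d: dict) -> "FitResult":
        spec = ModelSpec(
            outcomes=d["spec"]["outcomes"],
            covariates=tuple(d["spec"]["covariates"]),
            levels=tuple(d["spec"]["levels"]),
            random_slope=d["spec"]["random_slope"],
            slope_levels=tuple(d["spec"]["slope_levels"]),
            quadrature_order=d["spec"]["quadrature_order"],
        )
        layout = Layout.from_spec(spec)
        theta = np.asarray(d["theta"])
        cov = None if d["cov"] is None else np.asarray(d["cov"])
        return cls(
            spec=spec, params=layout.unpack(theta), theta=theta,
            loglik=d["loglik"], cov=cov, converged=d["converged"],
            n_iter=d["n_iter"], n_evals=d["n_evals"], grad_norm=d["grad_norm"],
            or_table=pd.DataFrame(d["or_table"]),
            variance_table=pd.DataFrame(d["variance_table"]),
            psd_repaired=d["psd_repaired"], layout=layout,
        )


def _plain_logistic_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Internal analytic-gradient logistic MLE used for starting values."""
    yf = y.astype(float)

    def nll(b):
        eta = X @ b
        return float(np.logaddexp(0.0, (1.0 - 2.0 * yf) * eta).sum())

    def grad(b):
        return X.T @ (expit(X @ b) - yf)

    res = minimize(nll, np.zeros(X.shape[1]), jac=grad, method="L-BFGS-B")
    return res.x


def _check_separation(design: StackedDesign) -> None:
    for k, name in enumerate(design.spec.outcome_names):
        ys = design.y[design.outcome_idx == k]
        if ys.min() == ys.max():
            raise SeparationError(
                f"outcome {name!r} is constant (all {int(ys[0])}); "
                "the logistic MLE does not exist"
            )


def _or_tables(spec: ModelSpec, layout: Layout, params: ModelParams,
               cov: np.ndarray | None) -> tuple[pd.DataFrame, pd.DataFrame]:
    p1 = layout.n_covariates + 1
    se_all = (np.full(layout.size, np.nan) if cov is None
              else np.sqrt(np.maximum(np.diag(cov), 0.0)))
    rows = []
    coef_names = ["Intercept"] + [DISPLAY_NAMES.get(c, c) for c in spec.covariates]
    for k, out in enumerate(spec.outcome_names):
        for j, nm in enumerate(coef_names):
            b = params.beta[k, j]
            se = se_all[k * p1 + j]
            z = b / se if se > 0 else np.nan
            rows.append({
                "outcome": out, "name": nm, "logodds": b, "se": se,
                "OR": np.exp(b), "z": z,
                "p": 2.0 * norm.sf(abs(z)) if np.isfinite(z) else np.nan,
            })
    or_table = pd.DataFrame(rows)

    vrows = []
    for k, sname in enumerate(layout.sigma_names):
        s = getattr(params, sname)
        se_log = se_all[layout.n_beta + k]
        vrows.append({
            "component": sname, "sigma": s, "variance": s ** 2,
            "se_log_sigma": se_log,
            "se_variance": 2.0 * s ** 2 * se_log if np.isfinite(se_log) else np.nan,
        })
    return or_table, pd.DataFrame(vrows)


def fit(design: StackedDesign, *, order: int | None = None,
        start: ModelParams | np.ndarray | None = None, max_iter: int = 300,
        gtol: float = 1e-5, compute_information: bool = True,
        information_rel_step: float = 1e-4) -> FitResult:
    """Maximize the marginal log-likelihood by quasi-Newton (L-BFGS-B) over
    the unconstrained packed parameters.

    Default start: per-outcome plain-logistic coefficients with every active
    standard deviation at 0.1. Log-SDs are box-bounded in [-10, 5] so a
    variance shrinking to the boundary cannot stall the line search.
    """
    spec = design.spec
    _check_separation(design)
    layout = Layout.from_spec(spec)
    rule = gauss_hermite_rule(order if order is not None else spec.quadrature_order)

    if start is None:
        betas = []
        for k in range(spec.n_outcomes):
            m = design.outcome_idx == k
            betas.append(_plain_logistic_beta(design.X[m], design.y[m]))
        start_params = ModelParams(beta=np.vstack(betas))
        for s in layout.sigma_names:
            setattr(start_params, s, 0.1)
        x0 = layout.pack(start_params)
    elif isinstance(start, ModelParams):
        x0 = layout.pack(start)
    else:
        x0 = np.asarray(start, dtype=float)

    n_evals = 0
    use_score = spec.random_slope is None

    if use_score:
        def negloglik(theta):
            nonlocal n_evals
            n_evals += 1
            ll, gr = marginal_loglik_and_grad(design, layout.unpack(theta), rule)
            return -ll, -gr
    else:
        def negloglik(theta):
            nonlocal n_evals
            n_evals += 1
            return -marginal_loglik(design, layout.unpack(theta), rule)

    bounds = [(None, None)] * layout.n_beta + [(-10.0, 5.0)] * len(layout.sigma_names)
    res = minimize(negloglik, x0, jac=use_score or None, method="L-BFGS-B",
                   bounds=bounds,
                   options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-11})
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"optimizer did not report convergence: {res.message}",
                      ConvergenceWarning)

    params = layout.unpack(res.x)
    cov = None
    repaired = False
    if compute_information:
        H = observed_information(design, res.x, rule=rule, layout=layout,
                                 rel_step=information_rel_step)
        cov, repaired = _safe_inverse(H)

    or_table, variance_table = _or_tables(spec, layout, params, cov)
    return FitResult(
        spec=spec, params=params, theta=res.x, loglik=-float(res.fun),
        cov=cov, converged=converged, n_iter=int(res.nit),
        n_evals=n_evals, grad_norm=float(np.max(np.abs(res.jac))),
        or_table=or_table, variance_table=variance_table,
        psd_repaired=repaired, layout=layout,
    )


def odds_ratio_table(fit_result: FitResult) -> pd.DataFrame:
    """Per-coefficient odds ratios with two-sided Wald p-values (variance
    components are reported separately in ``variance_table``)."""
    return fit_result.or_table[["outcome", "name", "OR", "p"]].copy()
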