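"""Independent numerical oracles used by the tests.

These deliberately avoid the package's Gauss-Hermite code path: the triple
integral is evaluated on dense trapezoid grids truncated at +-8 standard
deviations (the integrand is smooth with Gaussian tails, so the truncated
trapezoid rule converges far below the tolerances asserted against it).
"""

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from jointglmm.design import fixed_predictor
from jointglmm.estimation import bernoulli_loglik


def _grid(sigma, npts):
    x = np.linspace(-8.0 * sigma, 8.0 * sigma, npts)
    h = x[1] - x[0]
    tw = np.full(npts, h)
    tw[0] = tw[-1] = h / 2.0
    return x, norm.logpdf(x, 0.0, sigma) + np.log(tw)


def trapezoid_triple_loglik(design, params, npts=401, chunk=2000):
    """Marginal log-likelihood of a small one-division one-cluster design by
    dense-grid integration over (division, cluster, woman) effects."""
    assert design.n_divisions == 1 and design.n_clusters == 1
    eta0 = fixed_predictor(design, params)
    bd, lwd = _grid(params.sigma_div, npts)
    bc, lwc = _grid(params.sigma_clu, npts)
    u, lwu = _grid(params.sigma_u, npts)
    T = (bd[:, None] + bc[None, :]).ravel()
    tot = np.zeros(len(T))
    for j in range(design.n_women):
        r0, r1 = design.woman_row_starts[j], design.woman_row_starts[j + 1]
        for a in range(0, len(T), chunk):
            Tc = T[a:a + chunk]
            llj = bernoulli_loglik(
                design.y[r0:r1, None, None],
                eta0[r0:r1, None, None] + Tc[None, :, None] + u[None, None, :],
            ).sum(axis=0)
            tot[a:a + chunk] += logsumexp(llj + lwu[None, :], axis=1)
    M = tot.reshape(npts, npts) + lwc[None, :]
    return float(logsumexp(logsumexp(M, axis=1) + lwd))
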