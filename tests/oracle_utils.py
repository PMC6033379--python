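"""Shared independent oracles for the test suite."""

import numpy as np


def gauss_legendre_marginal(mu, sigma, x, J, nodes=160):
    """Log marginal density of x[J] obtained by integrating the full 4-D
    Gaussian density over the missing coordinates with tensor-product
    Gauss-Legendre quadrature (independent of the engine's submatrix path)."""
    from numpy.polynomial.legendre import leggauss
    from scipy.stats import multivariate_normal

    miss = [d - 1 for d in range(1, 5) if d not in J]
    obs = [d - 1 for d in sorted(J)]
    sd = np.sqrt(np.diag(sigma))
    pts, wts = leggauss(nodes)
    axes, weights = [], []
    for d in miss:
        lo, hi = mu[d] - 12 * sd[d], mu[d] + 12 * sd[d]
        axes.append(0.5 * (hi - lo) * pts + 0.5 * (hi + lo))
        weights.append(0.5 * (hi - lo) * wts)
    grids = np.meshgrid(*axes, indexing="ij")
    full = np.empty(grids[0].shape + (4,))
    for d, g in zip(miss, grids):
        full[..., d] = g
    for d in obs:
        full[..., d] = x[d]
    dens = multivariate_normal(mu, sigma).pdf(full.reshape(-1, 4)).reshape(grids[0].shape)
    w = weights[0]
    for other in weights[1:]:
        w = np.multiply.outer(w, other)
    return float(np.log(np.sum(dens * w)))


def joint_log_score(path, log_e, transition):
    """Log joint density of one hidden path given explicit log emissions."""
    m = transition.shape[0]
    logp = -np.log(m) + log_e[0, path[0]]
    for i in range(1, len(path)):
        logp += np.log(transition[path[i - 1], path[i]]) + log_e[i, path[i]]
    return logp
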