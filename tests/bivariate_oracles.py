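"""Shared independent oracle for the bivariate marginal likelihood."""

import numpy as np
from scipy import integrate
from scipy.special import gammaln

TOY = np.array([[10, 2, 3, 15], [20, 5, 8, 40], [7, 1, 2, 9]], dtype=float)


def brute_force_loglik(counts, mu, sigma, grid_n=2001, lim=8.0):
    """Dense 2-D Simpson integration of the binomial-normal integrand;
    independent of the quadrature code path."""
    sigma_inv = np.linalg.inv(sigma)
    _, logdet = np.linalg.slogdet(sigma)
    g = np.linspace(-lim, lim, grid_n)
    total = 0.0
    for tp, fp, fn, tn in counts:
        y = np.array([tp, tn])
        n = np.array([tp + fn, fp + tn])
        logc = float((gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)).sum())
        t1, t2 = np.meshgrid(g + mu[0], g + mu[1], indexing="ij")
        f = y[0] * t1 - n[0] * np.logaddexp(0, t1) + y[1] * t2 - n[1] * np.logaddexp(0, t2)
        d1, d2 = t1 - mu[0], t2 - mu[1]
        quad = sigma_inv[0, 0] * d1**2 + 2 * sigma_inv[0, 1] * d1 * d2 + sigma_inv[1, 1] * d2**2
        f += -np.log(2 * np.pi) - 0.5 * logdet - 0.5 * quad
        m = f.max()
        val = integrate.simpson(integrate.simpson(np.exp(f - m), x=g, axis=1), x=g)
        total += logc + m + np.log(val)
    return total
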