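"""Independent fine-grid oracle for the posterior of beta.

Deliberately separate from the package's quadrature path: plain vectorized
grid integration of the weighted-likelihood posterior, used to validate the
adaptive-quadrature results.
"""

import numpy as np
from scipy.integrate import cumulative_trapezoid


def grid_posterior(snapshots, prior_mean, prior_sd, n_points=100_000):
    """Return (posterior mean, quantile function) from grid integration."""
    beta = np.linspace(prior_mean - 10 * prior_sd, prior_mean + 10 * prior_sd,
                       n_points)
    x = np.array([s.dose_label for s in snapshots])
    y = np.array([s.tox for s in snapshots])
    w = np.array([s.weight for s in snapshots])
    dens = np.exp(-0.5 * ((beta - prior_mean) / prior_sd) ** 2)
    if len(snapshots):
        p = (x[None, :] ** np.exp(beta)[:, None]) * w[None, :]
        lik = np.prod(np.where(y[None, :] == 1, p, 1.0 - p), axis=1)
        dens = dens * lik
    mean = float(np.sum(beta * dens) / np.sum(dens))
    cdf = cumulative_trapezoid(dens, beta, initial=0.0)
    cdf /= cdf[-1]

    def quantile(q):
        return float(np.interp(q, cdf, beta))

    return mean, quantile
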