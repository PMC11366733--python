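"""Independent brute-force oracle for the JZS marginal likelihood.

Integrates the joint density over a dense 3-D grid in
(beta, log sigma^2, log g) by trapezoid rule, sharing nothing with the
closed-form/quadrature implementation beyond the model definition.
"""

import numpy as np
from scipy.special import logsumexp

SQRT2_OVER_4 = np.sqrt(2.0) / 4.0


def grid_log_marginal(y, x, rscale=SQRT2_OVER_4, n_beta=201, n_u=201, n_v=201):
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = y.size
    xtx = x @ x
    xty = x @ y
    yty = y @ y
    bhat = xty / xtx
    ssr = max(yty - xty**2 / xtx, 1e-12)
    s2hat = ssr / n
    se = np.sqrt(s2hat / xtx)

    beta = np.linspace(bhat - 12 * se - 0.5 * abs(bhat), bhat + 12 * se + 0.5 * abs(bhat), n_beta)
    u = np.linspace(np.log(s2hat) - 6.0, np.log(s2hat) + 6.0, n_u)  # log sigma^2
    v = np.linspace(-14.0, 14.0, n_v)  # log g

    B, U, V = np.meshgrid(beta, u, v, indexing="ij", sparse=True)
    s2 = np.exp(U)
    g = np.exp(V)

    ssr_b = yty - 2 * B * xty + B**2 * xtx
    loglik = -0.5 * n * np.log(2 * np.pi) - 0.5 * n * U - 0.5 * ssr_b / s2
    var_b = g * s2 * n / xtx
    lp_beta = -0.5 * np.log(2 * np.pi * var_b) - 0.5 * B**2 / var_b
    log_c = np.log(rscale) - 0.5 * np.log(2.0) - 0.5 * np.log(np.pi)
    lp_g = log_c - 0.5 * V - 0.5 * rscale**2 * np.exp(-V)  # prior + Jacobian
    # Jeffreys sigma^2 prior + log-Jacobian contribute exactly zero.
    logf = loglik + lp_beta + lp_g

    def log_trapz_weights(grid):
        w = np.full(grid.size, 1.0)
        w[0] = w[-1] = 0.5
        return np.log(w * (grid[1] - grid[0]))

    logf = (
        logf
        + log_trapz_weights(beta)[:, None, None]
        + log_trapz_weights(u)[None, :, None]
        + log_trapz_weights(v)[None, None, :]
    )
    return float(logsumexp(logf))
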