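"""No-intercept Jeffreys-Zellner-Siow regression marginal likelihoods.

Model for one participant x phase: shift y_i = beta * x_i + eps_i with
eps_i ~ Normal(0, sigma^2), where x is the (possibly transformed) advice
distance. Priors:

    p(sigma^2)            ∝ 1 / sigma^2
    beta | sigma^2, g     ~ Normal(0, g * sigma^2 * n / (x'x))
    g                     ~ InverseGamma(1/2, r^2 / 2)

i.e. the Zellner-Siow set-up, which makes the marginal prior on the
standardised slope a Cauchy with scale r (default r = sqrt(2)/4, the
"medium" regression scale). There is no intercept term. The improper
sigma^2 prior contributes the same constant to every model, so Bayes
factors and posterior model probabilities are well defined.

Conditional on g, beta and sigma^2 integrate out in closed form:

    log p(y | g) = lgamma(n/2) - (n/2) log(pi)
                   - 0.5 log(1 + g n) - (n/2) log Q(g)

    Q(g) = y'y - (g n / (1 + g n)) * (x'y)^2 / (x'x)

leaving a one-dimensional integral over g, evaluated here by adaptive
quadrature on the log-g axis with max-shifting for stability. Posterior
moments of beta and sigma^2 are obtained from the same mixture over g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special

__all__ = ["DEFAULT_RSCALE", "JzsQuadratureFit", "jzs_log_marginal_quadrature", "fit_jzs_quadrature"]

#: BayesFactor's "medium" regression prior scale.
DEFAULT_RSCALE = math.sqrt(2.0) / 4.0

_TMIN, _TMAX = -60.0, 60.0  # integration support on t = log g


def _suff_stats(y, x):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D arrays of equal length")
    n = y.size
    if n < 3:
        raise ValueError("need n >= 3 observations to fit")
    xtx = float(x @ x)
    if xtx <= 0:
        raise ValueError("degenerate predictor: x'x must be positive")
    return n, float(y @ y), float(x @ y), xtx


def _log_py_given_g(g, n, yty, xty, xtx):
    shrink = g * n / (1.0 + g * n)
    q = yty - shrink * xty**2 / xtx
    q = np.maximum(q, 1e-300)  # exact collinearity guard
    return (
        special.gammaln(n / 2.0)
        - (n / 2.0) * math.log(math.pi)
        - 0.5 * np.log1p(g * n)
        - (n / 2.0) * np.log(q)
    )


def _log_integrand(t, n, yty, xty, xtx, rscale):
    # t = log g; includes the InverseGamma(1/2, r^2/2) prior and Jacobian.
    g = np.exp(t)
    log_c = math.log(rscale) - 0.5 * math.log(2.0) - 0.5 * math.log(math.pi)
    return _log_py_given_g(g, n, yty, xty, xtx) + log_c - 0.5 * t - 0.5 * rscale**2 * np.exp(-t)


@dataclass(frozen=True)
class JzsQuadratureFit:
    """Quadrature fit of one model to one participant x phase."""

    log_marginal: float
    slope_mean: float
    slope_sd: float
    sigma_mean: float
    n_obs: int


def _quad_pieces(fun, tmode, epsrel):
    i1, _ = integrate.quad(fun, _TMIN, tmode, epsabs=0.0, epsrel=epsrel, limit=300)
    i2, _ = integrate.quad(fun, tmode, _TMAX, epsabs=0.0, epsrel=epsrel, limit=300)
    return i1 + i2


def jzs_log_marginal_quadrature(y, x, rscale: float = DEFAULT_RSCALE, epsrel: float = 1e-10) -> float:
    """Log marginal likelihood of y under y = beta x + eps, JZS prior on beta."""
    return fit_jzs_quadrature(y, x, rscale=rscale, epsrel=epsrel).log_marginal


def fit_jzs_quadrature(
    y, x, rscale: float = DEFAULT_RSCALE, epsrel: float = 1e-10
) -> JzsQuadratureFit:
    """Log marginal likelihood plus posterior slope / residual-SD summaries.

    E[beta | y] and E[beta^2 | y] are mixtures over the posterior of g of
    the conditional ridge mean b(g) = (gn/(1+gn)) x'y/x'x and its second
    moment; E[sigma^2 | g, y] = Q(g)/(n-2). All integrals share the same
    quadrature grid treatment (split at the mode of the integrand in
    t = log g, max-shifted exponentials).
    """
    if rscale <= 0:
        raise ValueError("rscale must be positive")
    n, yty, xty, xtx = _suff_stats(y, x)

    def logf(t):
        return _log_integrand(t, n, yty, xty, xtx, rscale)

    res = optimize.minimize_scalar(
        lambda t: -logf(t), bounds=(_TMIN, _TMAX), method="bounded"
    )
    tmode = float(res.x)
    fmax = float(logf(tmode))
    if not np.isfinite(fmax):
        raise FloatingPointError("JZS integrand is not finite at its mode")

    def density(t):
        return np.exp(logf(t) - fmax)

    z = _quad_pieces(density, tmode, epsrel)
    log_marginal = fmax + math.log(z)

    def moment(fun_of_t):
        val = _quad_pieces(lambda t: fun_of_t(t) * density(t), tmode, epsrel)
        return val / z

    def b_of_t(t):
        g = np.exp(t)
        return (g * n / (1.0 + g * n)) * xty / xtx

    def esig2_of_t(t):
        g = np.exp(t)
        shrink = g * n / (1.0 + g * n)
        q = yty - shrink * xty**2 / xtx
        return max(q, 1e-300) / (n - 2.0) if n > 2 else float("nan")

    def eb2_of_t(t):
        g = np.exp(t)
        cond_var = esig2_of_t(t) / (xtx * (1.0 + 1.0 / (g * n)))
        return b_of_t(t) ** 2 + cond_var

    slope_mean = moment(b_of_t)
    slope_m2 = moment(eb2_of_t)
    sigma2_mean = moment(esig2_of_t)
    slope_var = max(slope_m2 - slope_mean**2, 0.0)
    return JzsQuadratureFit(
        log_marginal=float(log_marginal),
        slope_mean=float(slope_mean),
        slope_sd=float(math.sqrt(slope_var)),
        sigma_mean=float(math.sqrt(sigma2_mean)),
        n_obs=n,
    )
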