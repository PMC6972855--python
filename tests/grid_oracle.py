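"""Vectorized brute-force grid oracles, independent of the fitting code.

These re-implement the mixture log-likelihood directly with scipy.stats
building blocks and locate optima by exhaustive lattice refinement, so
they share no optimizer machinery with the package's fitting path.
"""

import numpy as np
from scipy.special import expit
from scipy.stats import norm


def mixture_loglik_batch(theta, X, y, sigma, lam):
    """Log-likelihood for a batch of theta vectors (rows: (gamma, beta))."""
    theta = np.atleast_2d(theta)
    k = X.shape[1]
    eta = np.clip(theta[:, :k] @ X.T, -30.0, 30.0)  # (B, n)
    mu = theta[:, k:] @ X.T
    p = expit(eta)
    pmv = y == 0
    out = np.zeros(theta.shape[0])
    if pmv.any():
        z = (lam - mu[:, pmv]) / sigma
        out += np.log(p[:, pmv] + (1 - p[:, pmv]) * norm.cdf(z)).sum(axis=1)
    obs = ~pmv
    if obs.any():
        r = (np.log(y[obs])[None, :] - mu[:, obs]) / sigma
        out += (
            np.log(1 - p[:, obs]) + norm.logpdf(r) - np.log(sigma)
        ).sum(axis=1)
    return out


def grid_max_theta(X, y, sigma, lam, center, half_width=3.0, stop=5e-4):
    """Iteratively refined 4-D lattice maximization of the likelihood."""
    center = np.asarray(center, dtype=float)
    width = half_width
    best_ll = -np.inf
    while width > stop:
        axes = [np.linspace(c - width, c + width, 9) for c in center]
        pts = np.stack(
            [g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1
        )
        lls = mixture_loglik_batch(pts, X, y, sigma, lam)
        i = int(np.argmax(lls))
        center, best_ll = pts[i], float(lls[i])
        width /= 4.0
    return best_ll, center


def grid_max_sigma(X, y, theta, lam, log_prior_fn=None, resolution=1e-4):
    """Exhaustive 1-D search for sigma on a log sigma^2 lattice."""
    theta = np.asarray(theta, dtype=float)
    k = X.shape[1]
    eta = np.clip(X @ theta[:k], -30.0, 30.0)
    mu = X @ theta[k:]
    p = expit(eta)
    t = np.arange(np.log(1e-4), np.log(1e4), resolution)
    sig = np.exp(0.5 * t)  # (T,)
    pmv = y == 0
    ll = np.zeros(t.size)
    if pmv.any():
        z = (lam - mu[pmv])[None, :] / sig[:, None]
        ll += np.log(p[pmv][None, :] + (1 - p[pmv])[None, :] * norm.cdf(z)).sum(axis=1)
    obs = ~pmv
    if obs.any():
        r = (np.log(y[obs]) - mu[obs])[None, :] / sig[:, None]
        ll += (norm.logpdf(r) - np.log(sig)[:, None]).sum(axis=1)
        ll += np.log(1 - p[obs]).sum()
    if log_prior_fn is not None:
        ll = ll + log_prior_fn(np.exp(t))
    return float(sig[int(np.argmax(ll))])
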