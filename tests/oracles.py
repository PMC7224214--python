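"""Brute-force density oracles used to verify the conjugate conditionals.

Each oracle evaluates prior × likelihood for one scalar (or small vector)
on a fine grid and normalizes numerically, independently of the conjugate
algebra it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import invgamma, norm


def kl_grid(p: np.ndarray, q: np.ndarray, dx: float) -> float:
    """Discrete KL divergence between two gridded, normalized densities."""
    p = p / (p.sum() * dx)
    q = q / (q.sum() * dx)
    mask = p > 1e-300
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])) * dx)


def gaussian_conditional_oracle(
    weights: np.ndarray,
    targets: np.ndarray,
    prior_var: float,
    noise_var: float,
    grid: np.ndarray,
) -> np.ndarray:
    """Unnormalized density of theta with prior N(0, prior_var) and
    observations targets[i] ~ N(weights[i] * theta, noise_var)."""
    logp = -0.5 * grid**2 / prior_var
    for w, d in zip(weights, targets):
        logp = logp - 0.5 * (d - w * grid) ** 2 / noise_var
    logp -= logp.max()
    return np.exp(logp)


def sigma2_conditional_oracle(
    alpha: float, beta: float, residuals: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Unnormalized density of the noise variance given residuals."""
    logp = invgamma.logpdf(grid, alpha, scale=beta)
    n = residuals.size
    sse = float((residuals**2).sum())
    logp = logp - 0.5 * n * np.log(grid) - 0.5 * sse / grid
    logp -= logp.max()
    return np.exp(logp)


def marginal_loglik_quadrature(
    z: np.ndarray,
    Xk: np.ndarray,
    sigma2_a: float,
    sigma2_e: float,
    half_width: float = 12.0,
    n_points: int = 401,
) -> float:
    """log ∫ N(a; 0, sigma2_a I) Π_m N(z_m; a'X[:, m], sigma2_e) da by
    tensor-grid quadrature over the strength vector (1 or 2 TFs)."""
    q = Xk.shape[0]
    axis = np.linspace(-half_width, half_width, n_points)
    da = axis[1] - axis[0]
    if q == 1:
        mean = np.outer(axis, Xk[0])
        loglik = norm.logpdf(z, mean, np.sqrt(sigma2_e)).sum(axis=1)
        logprior = norm.logpdf(axis, 0.0, np.sqrt(sigma2_a))
        total = loglik + logprior
        m = total.max()
        return float(m + np.log(np.exp(total - m).sum() * da))
    if q == 2:
        a1, a2 = np.meshgrid(axis, axis, indexing="ij")
        mean = a1[..., None] * Xk[0] + a2[..., None] * Xk[1]
        loglik = norm.logpdf(z, mean, np.sqrt(sigma2_e)).sum(axis=-1)
        logprior = norm.logpdf(a1, 0, np.sqrt(sigma2_a)) + norm.logpdf(
            a2, 0, np.sqrt(sigma2_a)
        )
        total = loglik + logprior
        m = total.max()
        return float(m + np.log(np.exp(total - m).sum() * da * da))
    raise ValueError("quadrature oracle supports 1 or 2 TFs only")
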