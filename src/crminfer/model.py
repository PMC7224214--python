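"""Hierarchical Bayesian log-linear model of CRM-driven gene expression.

The observation model is linear in log space: with Y the log-transformed,
per-gene centered expression (genes × samples),

    y[n, m] = sum_t a[n, t] * b[c_n, t] * x[t, m] + r[n] + e[n, m]

where ``c_n`` indexes the candidate module assigned to gene n, ``b`` is the
binary candidate matrix, ``a[n, t]`` is the regulation strength of TF t on
gene n (positive = activation, negative = repression, defined only for TFs
in the assigned module), ``x[t, m]`` is the latent activity of TF t in
sample m, ``r[n]`` a baseline residual left over by imperfect centering and
``e[n, m]`` i.i.d. Gaussian noise with variance ``sigma2_e``.

Priors: zero-mean Gaussians on x, on active a, and on r, with fixed
variances ``sigma2_x``, ``sigma2_a``, ``sigma2_r``; a uniform prior over
each gene's compatible modules; and a conjugate inverse-gamma(alpha, beta)
prior on the noise variance. All full conditionals are then available in
closed form (Gaussian for x, a, r; inverse-gamma for sigma2_e; a discrete
distribution over compatible modules for c_n), which is what the Gibbs
sampler in :mod:`crminfer.gibbs` cycles through.

When scoring candidate modules for a gene, the gene's strength vector is
integrated out analytically under its Gaussian prior, so the module score
is the marginal likelihood

    y[n, :] - r[n] ~ N(0, sigma2_a * X_k' X_k + sigma2_e * I)

with X_k the rows of X for the module's TFs. After a module is chosen the
strength vector is redrawn from its exact multivariate conditional; the
pair of moves is a blocked draw of (c_n, a_n) and leaves the posterior
invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, solve_triangular

__all__ = [
    "Hyperparameters",
    "ModelState",
    "ZERO",
    "residual",
    "cond_x",
    "cond_a",
    "cond_r",
    "cond_sigma2_e",
    "module_log_marginal",
    "module_posterior",
    "draw_strengths",
]

#: Sentinel returned by :func:`cond_a` when the TF is not in the gene's
#: current module: the strength is structurally fixed at zero.
ZERO = "zero"

_JITTER = 1e-10


@dataclass(frozen=True)
class Hyperparameters:
    """Fixed prior variances and the inverse-gamma noise prior.

    Defaults assume expression on the mean-centered natural-log scale:
    unit-variance priors on TF activities and regulation strengths, a small
    variance on the baseline residual (which only mops up centering error),
    and a weak inverse-gamma(1, 1) prior on the noise variance.
    """

    sigma2_x: float = 1.0
    sigma2_a: float = 1.0
    sigma2_r: float = 0.1
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma2_x", "sigma2_a", "sigma2_r", "alpha", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class ModelState:
    """One Gibbs chain's current variable values.

    ``E`` caches the residual matrix Y - (A∘B_C) X - R; the sweep updates it
    incrementally and it must always equal :func:`residual` of the state.
    """

    X: np.ndarray  # T×M TF activities
    A: np.ndarray  # N×T strengths; nonzero only on the assigned module's TFs
    C: np.ndarray  # length-N module indices
    R: np.ndarray  # length-N baseline residuals
    sigma2_e: float
    E: np.ndarray | None = None  # N×M cached residual

    def validate(self, crms, compat) -> None:
        """Check structural invariants (support of A, compatibility, sigma2_e)."""
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be positive")
        active = crms.B[self.C].astype(bool)
        if np.any((self.A != 0) & ~active):
            raise ValueError("nonzero strength outside the assigned module")
        for n, k in enumerate(self.C):
            if k not in compat[n]:
                raise ValueError(f"gene {n} assigned an incompatible module {k}")


def residual(state: ModelState, Y: np.ndarray, crms) -> np.ndarray:
    """E[n, m] = Y[n, m] - sum_t A[n, t]·b[C[n], t]·X[t, m] - R[n]."""
    W = state.A * crms.B[state.C]  # N×T effective strengths
    return Y - W @ state.X - state.R[:, None]


def cond_x(
    t: int, m: int, state: ModelState, Y: np.ndarray, crms, hyper: Hyperparameters
) -> tuple[float, float]:
    """Conditional posterior N(mu, var) of the activity x[t, m].

    x[t, m] enters gene n's likelihood with weight w_n = A[n, t]·b[C[n], t];
    standard Gaussian conjugacy gives
    var = 1/(1/sigma2_x + Σ_n w_n²/sigma2_e), mu = var·Σ_n w_n·d_n / sigma2_e
    with d_n the residual with x[t, m]'s own contribution added back.
    """
    E = state.E if state.E is not None else residual(state, Y, crms)
    w = state.A[:, t] * crms.B[state.C, t]
    d = E[:, m] + w * state.X[t, m]
    var = 1.0 / (1.0 / hyper.sigma2_x + (w @ w) / state.sigma2_e)
    mu = var * (w @ d) / state.sigma2_e
    return float(mu), float(var)


def cond_a(
    n: int, t: int, state: ModelState, Y: np.ndarray, crms, hyper: Hyperparameters
):
    """Conditional posterior of the strength a[n, t], or ``ZERO``.

    If TF t is not in gene n's current module the strength is structurally
    zero and the sentinel is returned. Otherwise Gaussian conjugacy in the
    row regression y[n, :] on X[t, :] gives the (mu, var) pair.
    """
    if crms.B[state.C[n], t] == 0:
        return ZERO
    E = state.E if state.E is not None else residual(state, Y, crms)
    x = state.X[t]
    d = E[n] + state.A[n, t] * x
    var = 1.0 / (1.0 / hyper.sigma2_a + (x @ x) / state.sigma2_e)
    mu = var * (x @ d) / state.sigma2_e
    return float(mu), float(var)


def cond_r(
    n: int, state: ModelState, Y: np.ndarray, crms, hyper: Hyperparameters
) -> tuple[float, float]:
    """Conditional posterior N(mu, var) of the baseline residual r[n]."""
    E = state.E if state.E is not None else residual(state, Y, crms)
    d = E[n] + state.R[n]
    M = d.size
    var = 1.0 / (1.0 / hyper.sigma2_r + M / state.sigma2_e)
    mu = var * d.sum() / state.sigma2_e
    return float(mu), float(var)


def cond_sigma2_e(
    state: ModelState, Y: np.ndarray, crms, hyper: Hyperparameters
) -> tuple[float, float]:
    """Posterior inverse-gamma(alpha', beta') parameters of the noise variance.

    alpha' = alpha + N·M/2 and beta' = beta + SSE/2 with SSE the sum of
    squared residuals over all N·M expression cells.
    """
    E = state.E if state.E is not None else residual(state, Y, crms)
    sse = float((E * E).sum())
    n_cells = E.size
    return hyper.alpha + n_cells / 2.0, hyper.beta + sse / 2.0


def _marginal_factor(Xk: np.ndarray, sigma2_a: float, sigma2_e: float):
    """Cholesky factor of I_q + (sigma2_a/sigma2_e)·Xk Xk' plus its logdet."""
    q = Xk.shape[0]
    G = Xk @ Xk.T
    Mmat = np.eye(q) + (sigma2_a / sigma2_e) * G + _JITTER * np.eye(q)
    L = np.linalg.cholesky(Mmat)
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    return L, logdet


def module_log_marginal(
    n: int, k: int, state: ModelState, Y: np.ndarray, crms,
    hyper: Hyperparameters, compat=None,
) -> float:
    """Log marginal likelihood of gene n's expression under module k.

    The gene's strength vector is integrated out under its N(0, sigma2_a·I)
    prior, giving z = y[n, :] - r[n] ~ N(0, sigma2_a·X_k' X_k + sigma2_e·I).
    Evaluated in the q-dimensional dual form (q = module size), so the cost
    is O(q²·M) rather than O(M³); the background module reduces to an
    isotropic Gaussian. When a compatibility map is supplied, an assignment
    outside gene n's compatible set raises ``ValueError``.
    """
    if compat is not None and k not in compat[n]:
        raise ValueError(f"module {k} is not compatible with gene {n}")
    z = Y[n] - state.R[n]
    M = z.size
    s2e = state.sigma2_e
    base = -0.5 * M * np.log(2.0 * np.pi * s2e)
    zz = float(z @ z)
    tfs = crms.module_tfs(k)
    if tfs.size == 0:
        return float(base - 0.5 * zz / s2e)
    Xk = state.X[tfs]
    L, logdet = _marginal_factor(Xk, hyper.sigma2_a, s2e)
    v = Xk @ z
    u = solve_triangular(L, v, lower=True)
    quad = (zz - (hyper.sigma2_a / s2e) * float(u @ u)) / s2e
    return float(base - 0.5 * logdet - 0.5 * quad)


def module_posterior(
    n: int, state: ModelState, Y: np.ndarray, crms, compat, hyper: Hyperparameters
) -> np.ndarray:
    """Posterior probabilities over gene n's compatible modules.

    Uniform prior over the compatible set; probabilities are proportional to
    the marginal likelihoods, normalized through log-sum-exp.
    """
    ks = compat[n]
    logs = np.array(
        [module_log_marginal(n, int(k), state, Y, crms, hyper, compat) for k in ks]
    )
    logs -= logs.max()
    p = np.exp(logs)
    return p / p.sum()


def draw_strengths(
    n: int, k: int, state: ModelState, Y: np.ndarray, crms,
    hyper: Hyperparameters, rng: np.random.Generator
) -> np.ndarray:
    """Draw gene n's strength vector from its exact conditional under module k.

    Returns a full length-T row (zeros off the module). The conditional is
    multivariate normal with precision (1/sigma2_a)·I + X_k X_k'/sigma2_e
    and mean precision⁻¹ · X_k z / sigma2_e.
    """
    T = state.X.shape[0]
    row = np.zeros(T)
    tfs = crms.module_tfs(k)
    if tfs.size == 0:
        return row
    z = Y[n] - state.R[n]
    Xk = state.X[tfs]
    s2e = state.sigma2_e
    prec = np.eye(tfs.size) / hyper.sigma2_a + (Xk @ Xk.T) / s2e
    Lp = np.linalg.cholesky(prec + _JITTER * np.eye(tfs.size))
    mean = cho_solve((Lp, True), Xk @ z / s2e)
    # a = mean + Lp^{-T} eps gives covariance prec^{-1}
    eps = rng.standard_normal(tfs.size)
    row[tfs] = mean + solve_triangular(Lp.T, eps, lower=False)
    return row
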