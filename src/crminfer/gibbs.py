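"""Multi-chain Gibbs sampler: initialization, sweeps, convergence, pooling.

Several chains are started from independent random initializations and
advanced in lockstep. Convergence is monitored with the potential scale
reduction factor (PSRF) — the classic within- vs between-chain variance
ratio — over a set of monitored scalars; because the likelihood only
constrains the products a·x (a joint sign flip of a TF's activities and
strengths changes nothing), the monitored scalars are the *absolute* TF
activities |x[t, m]| together with each gene's total absolute active
strength, which are invariant under the sign symmetry. Once the maximum
PSRF drops below threshold, a fixed number of sweeps per chain is collected
and pooled into module sampling frequencies and posterior means.

Within one sweep the scan order is systematic: TF activities, regulation
strengths, baseline residuals, module assignments (with the gene's strength
vector redrawn as a block after each reassignment), then the noise
variance. The residual matrix is carried incrementally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Hyperparameters, ModelState, _JITTER, _marginal_factor, residual
from .outputs import PosteriorSummary

__all__ = [
    "ChainConfig",
    "ConvergenceReport",
    "SampleAccumulator",
    "init_state",
    "sweep",
    "psrf",
    "run",
]


@dataclass(frozen=True)
class ChainConfig:
    """Sampler schedule: chains, convergence monitoring, collection length."""

    n_chains: int = 3
    check_interval: int = 50
    psrf_threshold: float = 1.1
    max_burnin: int = 5000
    n_collect: int = 1000
    seed: int = 0
    #: Score module assignments with the current sampled strengths instead
    #: of marginalizing them (see :func:`sweep`); strengths then persist for
    #: every TF appearing in any of the gene's candidate modules.
    score_on_current_strengths: bool = False

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("convergence monitoring needs at least 2 chains")
        if self.psrf_threshold <= 1.0:
            raise ValueError("psrf_threshold must exceed 1")
        if self.n_collect < 1:
            raise ValueError("n_collect must be >= 1")


@dataclass
class ConvergenceReport:
    """Checkpointed PSRF trace and the convergence verdict."""

    checkpoints: pd.DataFrame  # sweep, max_psrf, mean_sigma2_e, loglik per chain
    converged: bool
    sweeps_to_convergence: int  # burn-in sweeps actually spent (per chain)


@dataclass
class SampleAccumulator:
    """Pooled post-convergence tallies across chains."""

    counts: np.ndarray  # N×K module-assignment counts
    sum_X: np.ndarray
    sum_A: np.ndarray
    sum_R: np.ndarray
    sum_sigma2_e: float = 0.0
    n_samples: int = 0

    @classmethod
    def empty(cls, N: int, K: int, T: int, M: int) -> "SampleAccumulator":
        return cls(
            counts=np.zeros((N, K), dtype=np.int64),
            sum_X=np.zeros((T, M)),
            sum_A=np.zeros((N, T)),
            sum_R=np.zeros(N),
        )

    def add(self, state: ModelState, crms=None) -> None:
        N = state.A.shape[0]
        self.counts[np.arange(N), state.C] += 1
        self.sum_X += state.X
        # only strengths active under the assigned module carry meaning
        if crms is not None:
            self.sum_A += state.A * crms.B[state.C]
        else:
            self.sum_A += state.A
        self.sum_R += state.R
        self.sum_sigma2_e += state.sigma2_e
        self.n_samples += 1

    def summarize(self, gene_ids: list[str]) -> PosteriorSummary:
        s = self.n_samples
        return PosteriorSummary(
            gene_ids=list(gene_ids),
            freq=self.counts / s,
            mean_X=self.sum_X / s,
            mean_A=self.sum_A / s,
            mean_R=self.sum_R / s,
            mean_sigma2_e=self.sum_sigma2_e / s,
        )


def init_state(
    Y: np.ndarray,
    crms,
    compat,
    hyper: Hyperparameters,
    rng: np.random.Generator,
    full_support: bool = False,
) -> ModelState:
    """Random initialization consistent with the binding prior.

    Each gene's module is drawn uniformly from its compatible set; active
    strengths and all activities are drawn from their Gaussian priors; the
    baseline residual is set to the per-gene mean leftover
    r[n] = mean_m(y[n, m] - Σ_t a·b·x) so the initial noise matrix has zero
    mean per gene; the noise variance is drawn from its inverse-gamma prior.

    With ``full_support`` (the condition-on-current-strengths sampler),
    strengths are initialized for every TF in any of the gene's candidate
    modules, not just the assigned one; the likelihood always masks them by
    the assigned module.
    """
    N, M = Y.shape
    T = crms.n_tfs
    C = np.array([rng.choice(ks) for ks in compat], dtype=np.int64)
    support = _bound_mask(compat, crms) if full_support else crms.B[C].astype(bool)
    A = np.where(support, rng.normal(0.0, np.sqrt(hyper.sigma2_a), (N, T)), 0.0)
    X = rng.normal(0.0, np.sqrt(hyper.sigma2_x), (T, M))
    fitted = (A * crms.B[C]) @ X
    R = (Y - fitted).mean(axis=1)
    sigma2_e = float(hyper.beta / rng.gamma(hyper.alpha))
    state = ModelState(X=X, A=A, C=C, R=R, sigma2_e=sigma2_e)
    state.E = residual(state, Y, crms)
    return state


def _size_groups(crms) -> dict:
    """Modules grouped by size q: q -> (module ids, position lookup, TF index rows)."""
    cache = getattr(crms, "_size_cache", None)
    if cache is not None:
        return cache
    sizes = crms.B.sum(axis=1)
    groups: dict = {}
    for q in np.unique(sizes[sizes > 0]):
        ks = np.flatnonzero(sizes == q)
        pos_of = np.full(crms.n_modules, -1, dtype=np.int64)
        pos_of[ks] = np.arange(ks.size)
        tf_idx = np.array([np.flatnonzero(crms.B[k]) for k in ks])
        groups[int(q)] = (ks, pos_of, tf_idx)
    try:
        crms._size_cache = groups
    except AttributeError:
        pass
    return groups


def _pair_arrays(compat, crms):
    """Flattened (gene, module) compatible pairs plus padded index matrices."""
    cache = getattr(compat, "_pair_cache", None)
    if cache is not None:
        return cache
    N = len(compat)
    lens = np.array([np.asarray(ks).size for ks in compat])
    cmax = int(lens.max())
    pad = np.full((N, cmax), crms.background_index, dtype=np.int64)
    mask = np.zeros((N, cmax), dtype=bool)
    for n, ks in enumerate(compat):
        ks = np.asarray(ks)
        pad[n, : ks.size] = ks
        mask[n, : ks.size] = True
    pair_n = np.repeat(np.arange(N), lens)
    pair_k = np.concatenate([np.asarray(ks) for ks in compat])
    starts = np.concatenate(([0], np.cumsum(lens)[:-1]))
    cache = (pair_n, pair_k, pad, mask, starts)
    try:
        compat._pair_cache = cache
    except AttributeError:
        pass
    return cache


def _bound_mask(compat, crms) -> np.ndarray:
    """N×T mask of TFs appearing in any of each gene's candidate modules."""
    cache = getattr(compat, "_bound_cache", None)
    if cache is not None:
        return cache
    N = len(compat)
    mask = np.zeros((N, crms.n_tfs), dtype=bool)
    for n, ks in enumerate(compat):
        mask[n] = crms.B[np.asarray(ks)].any(axis=0)
    try:
        compat._bound_cache = mask
    except AttributeError:
        pass
    return mask


def _check_finite(arr, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError(f"non-finite value encountered in {name}")


def sweep(
    state: ModelState,
    Y: np.ndarray,
    crms,
    compat,
    hyper: Hyperparameters,
    rng: np.random.Generator,
    update_x: bool = True,
    update_a: bool = True,
    update_r: bool = True,
    update_c: bool = True,
    update_sigma2: bool = True,
    score_on_current_strengths: bool = False,
) -> ModelState:
    """One full systematic Gibbs scan, updating the state in place.

    The ``update_*`` switches freeze individual variable blocks (useful for
    diagnostics such as sampling the noise variance on an otherwise fixed
    model); by default every block is updated. Returns the state.

    Two module-assignment moves are available. The default integrates the
    gene's strength vector out analytically when scoring candidate modules
    and then redraws it as a block — an exact collapsed Gibbs move with
    good mixing across module sizes. With ``score_on_current_strengths``,
    strengths persist for every TF in any of the gene's candidate modules
    (out-of-module ones refresh from their prior) and modules are scored by
    the likelihood under the current strength values. The two chains share
    the same stationary distribution, but the conditioned variant crosses
    between nested modules only through rare prior draws, so its finite-run
    sampling frequencies concentrate on modules whose regulators are
    currently well fitted — including weak ones.
    """
    N, M = Y.shape
    T = crms.n_tfs
    s2e = state.sigma2_e
    E = state.E if state.E is not None else residual(state, Y, crms)

    if update_x:
        # x[t, :] — across samples the conditionals are independent
        for t in range(T):
            w = state.A[:, t] * crms.B[state.C, t]
            D = E + np.outer(w, state.X[t])
            var = 1.0 / (1.0 / hyper.sigma2_x + (w @ w) / s2e)
            mu = var * (w @ D) / s2e
            state.X[t] = mu + np.sqrt(var) * rng.standard_normal(M)
            E = D - np.outer(w, state.X[t])
        _check_finite(state.X, "TF activity X")

    if update_a:
        # a[:, t] — across genes the conditionals are independent
        bound = _bound_mask(compat, crms) if score_on_current_strengths else None
        for t in range(T):
            active = crms.B[state.C, t].astype(bool)
            if bound is None and not active.any():
                continue
            x = state.X[t]
            contrib = np.where(active, state.A[:, t], 0.0)
            D = E + np.outer(contrib, x)
            var = 1.0 / (1.0 / hyper.sigma2_a + (x @ x) / s2e)
            mu = var * (D @ x) / s2e
            draws = mu + np.sqrt(var) * rng.standard_normal(N)
            if bound is None:
                a_new = np.where(active, draws, 0.0)
            else:
                # out-of-module candidate strengths have no likelihood term;
                # their conditional is the prior
                prior = np.sqrt(hyper.sigma2_a) * rng.standard_normal(N)
                a_new = np.where(active, draws, np.where(bound[:, t], prior, 0.0))
            state.A[:, t] = a_new
            E = D - np.outer(np.where(active, a_new, 0.0), x)
        _check_finite(state.A, "regulation strength A")

    if update_r:
        D = E + state.R[:, None]
        var = 1.0 / (1.0 / hyper.sigma2_r + M / s2e)
        mu = var * D.sum(axis=1) / s2e
        state.R = mu + np.sqrt(var) * rng.standard_normal(N)
        E = D - state.R[:, None]
        _check_finite(state.R, "baseline residual R")

    if update_c:
        # Given X, R and the noise variance, gene n's log marginal under
        # module k is -0.5*logdet_k - 0.5*(z'z - ratio * v'M_k^{-1}v)/s2e
        # with z = y_n - r_n, v = X_k z, M_k = I + ratio * X_k X_k' and
        # ratio = s2a/s2e. All (gene, module) compatible pairs are scored
        # with batched array operations, grouped by module size; the same
        # dual matrix M_k gives the strength conditional (precision M_k/s2a),
        # so its factors are reused for the blocked strength redraw.
        ratio = hyper.sigma2_a / s2e
        Z = Y - state.R[:, None]  # N×M
        zz = np.einsum("nm,nm->n", Z, Z)
        sizes = crms.B.sum(axis=1)
        pair_n, pair_k, pad, mask, starts = _pair_arrays(compat, crms)
        P = pair_n.size
        pair_scores = np.empty(P)
        pair_sizes = sizes[pair_k]
        bg = pair_sizes == 0
        pair_scores[bg] = -0.5 * zz[pair_n[bg]] / s2e
        groups = _size_groups(crms)  # q -> (ks, pos_of, tf_idx)
        if score_on_current_strengths:
            # likelihood of each candidate under the current strengths
            for q, (ks, pos_of, tf_idx) in groups.items():
                sel = np.flatnonzero(pair_sizes == q)
                pos = pos_of[pair_k[sel]]
                Xk = state.X[tf_idx]  # nq×q×M
                a_g = state.A[pair_n[sel][:, None], tf_idx[pos]]  # p×q
                resid_fit = Z[pair_n[sel]] - np.einsum(
                    "pq,pqm->pm", a_g, Xk[pos]
                )
                pair_scores[sel] = -0.5 * np.einsum(
                    "pm,pm->p", resid_fit, resid_fit
                ) / s2e
            logs = np.full(pad.shape, -np.inf)
            logs[mask] = pair_scores
            gumbel = -np.log(-np.log(rng.random(pad.shape)))
            C_new = pad[np.arange(N), np.argmax(logs + gumbel, axis=1)]
            state.C = C_new
            # strengths persist; refresh the residual under the new modules
            chosen_sizes = sizes[C_new]
            idx_bg = np.flatnonzero(chosen_sizes == 0)
            E[idx_bg] = Z[idx_bg]
            for q, (ks, pos_of, tf_idx) in groups.items():
                genes = np.flatnonzero(chosen_sizes == q)
                if genes.size == 0:
                    continue
                pos = pos_of[C_new[genes]]
                a_g = state.A[genes[:, None], tf_idx[pos]]
                E[genes] = Z[genes] - np.einsum(
                    "pq,pqm->pm", a_g, state.X[tf_idx][pos]
                )
            _check_finite(E, "module assignment C / residual")
            state.E = E
            if update_sigma2:
                sse = float((E * E).sum())
                alpha_post = hyper.alpha + N * M / 2.0
                beta_post = hyper.beta + sse / 2.0
                state.sigma2_e = float(beta_post / rng.gamma(alpha_post))
                if not np.isfinite(state.sigma2_e) or state.sigma2_e <= 0:
                    raise FloatingPointError(
                        "non-finite or non-positive value encountered in sigma2_e"
                    )
            return state
        stores = {}
        pair_pos = np.empty(P, dtype=np.int64)  # position within size class
        for q, (ks, pos_of, tf_idx) in groups.items():
            Xk = state.X[tf_idx]  # nq×q×M
            G = Xk @ Xk.transpose(0, 2, 1)
            eye = np.eye(q)
            Mmat = eye + ratio * G + _JITTER * eye
            L = np.linalg.cholesky(Mmat)
            logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
            Minv = np.linalg.inv(Mmat)
            # upper factor with Uc Uc' = (Mmat/s2a)^{-1}, the strength
            # conditional covariance
            Uc = np.sqrt(hyper.sigma2_a) * np.linalg.inv(L).transpose(0, 2, 1)
            sel = np.flatnonzero(pair_sizes == q)
            pos = pos_of[pair_k[sel]]
            v = np.einsum("pqm,pm->pq", Xk[pos], Z[pair_n[sel]])
            quad = zz[pair_n[sel]] - ratio * np.einsum(
                "pq,pqr,pr->p", v, Minv[pos], v
            )
            pair_scores[sel] = -0.5 * logdet[pos] - 0.5 * quad / s2e
            pair_pos[sel] = pos
            stores[q] = (sel, v, Minv, Uc, Xk, tf_idx)
        # Gumbel-max categorical draw over each gene's compatible modules
        logs = np.full(pad.shape, -np.inf)
        logs[mask] = pair_scores
        gumbel = -np.log(-np.log(rng.random(pad.shape)))
        col = np.argmax(logs + gumbel, axis=1)
        C_new = pad[np.arange(N), col]
        chosen_pair = starts + col  # flat pair index per gene
        state.C = C_new
        # blocked strength redraw per size class, fully vectorized
        A_new = np.zeros((N, T))
        chosen_sizes = sizes[C_new]
        idx_bg = np.flatnonzero(chosen_sizes == 0)
        E[idx_bg] = Z[idx_bg]
        for q in sorted(stores):
            sel, v, Minv, Uc, Xk, tf_idx = stores[q]
            genes = np.flatnonzero(chosen_sizes == q)
            if genes.size == 0:
                continue
            class_of = np.full(P, -1, dtype=np.int64)
            class_of[sel] = np.arange(sel.size)
            p_idx = class_of[chosen_pair[genes]]
            pos = pair_pos[chosen_pair[genes]]
            mean = ratio * np.einsum("pqr,pr->pq", Minv[pos], v[p_idx])
            eps = rng.standard_normal((genes.size, q))
            a = mean + np.einsum("pqr,pr->pq", Uc[pos], eps)
            A_new[genes[:, None], tf_idx[pos]] = a
            E[genes] = Z[genes] - np.einsum("pq,pqm->pm", a, Xk[pos])
        state.A = A_new
        _check_finite(state.A, "module assignment C / strengths")

    if update_sigma2:
        sse = float((E * E).sum())
        alpha_post = hyper.alpha + N * M / 2.0
        beta_post = hyper.beta + sse / 2.0
        state.sigma2_e = float(beta_post / rng.gamma(alpha_post))
        if not np.isfinite(state.sigma2_e) or state.sigma2_e <= 0:
            raise FloatingPointError(
                "non-finite or non-positive value encountered in sigma2_e"
            )

    state.E = E
    return state


def psrf(chains: list[np.ndarray] | np.ndarray) -> float:
    """Potential scale reduction factor for one monitored scalar.

    With L retained values in each of J chains, W the mean within-chain
    variance and B the between-chain variance of the chain means times L,
    the statistic is sqrt(((L-1)/L·W + B/L) / W). Values near 1 indicate the
    chains have mixed; a constant scalar returns 1 by convention and chains
    stuck at different constants return +inf.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 values each")
    return float(_psrf_many(arr[:, :, None])[0])


def _psrf_many(arr: np.ndarray) -> np.ndarray:
    """Vectorized PSRF over the last axis of a (chains, L, P) array."""
    J, L, _ = arr.shape
    means = arr.mean(axis=1)  # J×P
    W = arr.var(axis=1, ddof=1).mean(axis=0)  # P
    B = L * means.var(axis=0, ddof=1)  # P
    out = np.empty(W.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.sqrt(((L - 1) / L * W + B / L) / W)
    zero_w = W == 0
    out[~zero_w] = val[~zero_w]
    out[zero_w & (B == 0)] = 1.0
    out[zero_w & (B > 0)] = np.inf
    return out


def _monitored(state: ModelState, crms) -> np.ndarray:
    """Sign-symmetry-invariant scalars: |x| entries and active |a| row sums.

    The likelihood is invariant under jointly flipping the sign of a TF's
    activities and strengths, so raw x and a values are not comparable
    across chains; their absolute values are.
    """
    active_a = np.abs(state.A * crms.B[state.C]).sum(axis=1)
    return np.concatenate([np.abs(state.X).ravel(), active_a])


def _loglik(state: ModelState) -> float:
    E = state.E
    nm = E.size
    return float(
        -0.5 * nm * np.log(2.0 * np.pi * state.sigma2_e)
        - 0.5 * (E * E).sum() / state.sigma2_e
    )


def run(
    Y: np.ndarray,
    crms,
    compat,
    hyper: Hyperparameters,
    config: ChainConfig,
    gene_ids: list[str] | None = None,
) -> tuple[PosteriorSummary, ConvergenceReport]:
    """Burn in until the chains mix, then pool posterior samples.

    All chains advance together; every ``check_interval`` sweeps the maximum
    PSRF over the monitored scalars is computed from the second half of the
    burn-in history. Once it falls below ``psrf_threshold``, ``n_collect``
    further sweeps per chain are accumulated (pooled across chains) into
    module sampling frequencies and posterior means. If ``max_burnin`` is
    reached first, collection still happens but the report is flagged
    non-converged.
    """
    N, M = Y.shape
    T = crms.n_tfs
    K = crms.n_modules
    if gene_ids is None:
        gene_ids = [f"g{n}" for n in range(N)]
    seqs = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    rngs = [np.random.default_rng(s) for s in seqs]
    variant = config.score_on_current_strengths
    states = [
        init_state(Y, crms, compat, hyper, rng, full_support=variant)
        for rng in rngs
    ]

    histories: list[list[np.ndarray]] = [[] for _ in range(config.n_chains)]
    checkpoints = []
    converged = False
    sweeps_done = 0
    while sweeps_done < config.max_burnin:
        for state, rng in zip(states, rngs):
            sweep(state, Y, crms, compat, hyper, rng,
                  score_on_current_strengths=variant)
        sweeps_done += 1
        for hist, state in zip(histories, states):
            hist.append(_monitored(state, crms))
        if sweeps_done % config.check_interval == 0:
            half = sweeps_done // 2
            arr = np.stack([np.stack(h[half:]) for h in histories])
            max_psrf = float(_psrf_many(arr).max())
            checkpoints.append(
                {
                    "sweep": sweeps_done,
                    "max_psrf": max_psrf,
                    "mean_sigma2_e": float(
                        np.mean([s.sigma2_e for s in states])
                    ),
                    **{
                        f"loglik_chain{j}": _loglik(s)
                        for j, s in enumerate(states)
                    },
                }
            )
            if max_psrf < config.psrf_threshold:
                converged = True
                break
    if not converged:
        warnings.warn(
            f"chains not converged after {sweeps_done} sweeps "
            f"(max PSRF above {config.psrf_threshold}); results are partial",
            stacklevel=2,
        )

    acc = SampleAccumulator.empty(N, K, T, M)
    for _ in range(config.n_collect):
        for state, rng in zip(states, rngs):
            sweep(state, Y, crms, compat, hyper, rng,
                  score_on_current_strengths=variant)
            acc.add(state, crms)
    summary = acc.summarize(gene_ids)
    report = ConvergenceReport(
        checkpoints=pd.DataFrame(checkpoints),
        converged=converged,
        sweeps_to_convergence=sweeps_done,
    )
    return summary, report
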