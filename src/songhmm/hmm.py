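"""Gaussian-emission hidden Markov models of order 0, 1 and 2, fitted by
Variational Bayes.

The observation unit is the syllable: each syllable contributes one
3-dimensional acoustic feature vector (duration, mean pitch, mean Wiener
entropy) and occupies one hidden state.  An order-r model makes the next
state depend on the last r states.  Order 0 has no transition structure and
is exactly the Gaussian mixture model; order 2 is reduced to an equivalent
first-order chain over *context states* — ordered pairs of consecutive
states, with a dummy symbol padding the start of each bout — so a single
forward-backward routine serves all orders.

Inference is mean-field Variational Bayes with conjugate priors: Dirichlet
rows for the initial distribution and each transition row, and a
Normal–Wishart prior per state for the Gaussian mean and precision.  Each
iteration alternates an E-step (forward-backward under expected-log
parameters) with conjugate M-step updates, and records the variational
lower bound on the log marginal likelihood; the trace is non-decreasing and
its final value is the model-selection score.  The bound automatically
penalizes superfluous parameters, so comparing it across (order, K) grids
embodies a Bayesian Occam's razor.

Public surface follows the model/results convention: build a
:class:`GaussianHMM` from a :class:`~songhmm.pomm.SongDataset`, call
:meth:`~GaussianHMM.fit`, and read everything else off the returned
:class:`VBHMMResults`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp
from sklearn.cluster import KMeans

from .pomm import FEATURE_DIM, SongDataset

logger = logging.getLogger(__name__)

__all__ = [
    "DUMMY",
    "VBHyperparams",
    "ContextIndex",
    "expand_context",
    "forward_backward",
    "FeatureScaler",
    "GaussianHMM",
    "VBHMMResults",
    "VBPosterior",
    "PredictiveLogLik",
    "vb_fit",
    "gaussian_marginal_loglik",
]

#: Dummy state padding contexts before the start of a bout.
DUMMY = -1

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Hyperparameters
# ---------------------------------------------------------------------------

@dataclass
class VBHyperparams:
    """Conjugate prior settings shared by all states and transition rows.

    ``dirichlet_alpha0`` is the symmetric Dirichlet concentration for the
    initial distribution and every transition row.  The Normal–Wishart prior
    on (mean, precision) has mean ``m0`` (default: data mean), scale
    ``beta0``, scale matrix ``W0`` (default: inverse data covariance divided
    by ``nu0``, so the prior expected precision matches the data) and
    degrees of freedom ``nu0`` (default D+2, the smallest value with a
    finite expected covariance).
    """

    dirichlet_alpha0: float = 1.0
    m0: np.ndarray | None = None
    beta0: float = 1.0
    W0: np.ndarray | None = None
    nu0: float | None = None

    def resolve(self, X: np.ndarray):
        """Concrete (m0, beta0, W0, nu0) given the stacked training features."""
        D = X.shape[1]
        nu0 = float(self.nu0) if self.nu0 is not None else D + 2.0
        if nu0 <= D + 1:
            raise ValueError("nu0 must exceed feature_dim + 1")
        m0 = np.asarray(self.m0, float) if self.m0 is not None else X.mean(axis=0)
        if self.W0 is not None:
            W0 = np.asarray(self.W0, float)
        else:
            cov = np.cov(X.T) if len(X) > 1 else np.eye(D)
            cov = np.atleast_2d(cov) + 1e-6 * np.eye(D)
            W0 = np.linalg.inv(cov) / nu0
        if self.beta0 <= 0 or self.dirichlet_alpha0 <= 0:
            raise ValueError("beta0 and dirichlet_alpha0 must be positive")
        return m0, float(self.beta0), W0, nu0

    def to_dict(self):
        return {
            "dirichlet_alpha0": self.dirichlet_alpha0,
            "m0": None if self.m0 is None else np.asarray(self.m0).tolist(),
            "beta0": self.beta0,
            "W0": None if self.W0 is None else np.asarray(self.W0).tolist(),
            "nu0": self.nu0,
        }


# ---------------------------------------------------------------------------
# Context-state expansion
# ---------------------------------------------------------------------------

class ContextIndex:
    """Bijection between context tuples and dense integers.

    A context is the tuple of the last r states, with :data:`DUMMY` filling
    positions before the bout start.  For r=1 there are K contexts (identity
    mapping); for r=2 there are K dummy-prefixed contexts ``(DUMMY, b)``
    (indices 0..K-1) plus K^2 ordinary contexts ``(a, b)``, i.e. K^2 + K in
    total.  Appending state k to context (a, b) yields (b, k): transition
    support is structurally restricted, not learned.
    """

    def __init__(self, order: int, n_states: int):
        if order not in (1, 2):
            raise ValueError("context expansion is defined for orders 1 and 2 only")
        K = int(n_states)
        if K < 1:
            raise ValueError("n_states must be >= 1")
        self.order = order
        self.n_states = K
        if order == 1:
            self.contexts = [(k,) for k in range(K)]
        else:
            self.contexts = [(DUMMY, b) for b in range(K)]
            self.contexts += [(a, b) for a in range(K) for b in range(K)]
        self.index = {c: i for i, c in enumerate(self.contexts)}
        self.n_contexts = len(self.contexts)
        self.cur_state = np.array([c[-1] for c in self.contexts], dtype=int)
        # succ[c, k]: context reached by appending state k
        self.succ = np.empty((self.n_contexts, K), dtype=int)
        for i, c in enumerate(self.contexts):
            for k in range(K):
                self.succ[i, k] = self.index[(*c[1:], k)] if order == 2 else self.index[(k,)]
        #: context occupied at t=0 when the first state is k
        self.initial_context = np.array(
            [self.index[(k,)] if order == 1 else self.index[(DUMMY, k)] for k in range(K)]
        )

    def state_marginal(self, gamma_ctx: np.ndarray) -> np.ndarray:
        """Sum context posteriors over contexts sharing the same current state."""
        T = gamma_ctx.shape[0]
        out = np.zeros((T, self.n_states))
        np.add.at(out.T, self.cur_state, gamma_ctx.T)
        return out

    def expand_trans_matrix(self, log_A: np.ndarray) -> np.ndarray:
        """Full (C, C) log transition matrix from per-row scores ``log_A[c, k]``."""
        M = np.full((self.n_contexts, self.n_contexts), -np.inf)
        rows = np.repeat(np.arange(self.n_contexts), self.n_states)
        M[rows, self.succ.ravel()] = log_A.ravel()
        return M


def expand_context(order: int, n_states: int) -> ContextIndex:
    """Build the context index for an order-1 or order-2 chain (see class doc)."""
    return ContextIndex(order, n_states)


# ---------------------------------------------------------------------------
# Forward-backward
# ---------------------------------------------------------------------------

def forward_backward(log_obs: np.ndarray, log_init: np.ndarray, log_trans: np.ndarray):
    """Log-space forward-backward over a (context-)state chain.

    Parameters are expected-log scores: ``log_obs`` is (T, C), ``log_init``
    (C,), ``log_trans`` (C, C) (``-inf`` marks structurally forbidden
    moves).  Returns ``(gamma, xi, ll)`` where ``gamma`` is (T, C) with unit
    row sums, ``xi`` is (T-1, C, C) per-step joint posteriors, and ``ll`` is
    the log normalizer.  All computation is in log space, so sequences up to
    T ~ 1e4 pose no underflow risk.
    """
    gamma, xi_sum, ll, xi_steps = _forward_backward(log_obs, log_init, log_trans, keep_steps=True)
    return gamma, xi_steps, ll


def _forward_backward(log_obs, log_init, log_trans, keep_steps=False):
    # scaled linear-space recursions: each step is normalized and the log
    # scale factors accumulate into the log normalizer, so arbitrarily long
    # sequences neither under- nor overflow
    log_obs = np.asarray(log_obs, float)
    T, C = log_obs.shape
    bad = ~(np.isfinite(log_obs) | (log_obs == -np.inf))
    if bad.any():
        t, c = np.argwhere(bad)[0]
        raise FloatingPointError(f"non-finite emission score at position {t}, state {c}")
    with np.errstate(over="ignore"):
        A = np.exp(log_trans)
        pi = np.exp(log_init)
    shift = log_obs.max(axis=1)
    if not np.all(np.isfinite(shift)):
        raise FloatingPointError("a position has zero emission probability in every state")
    B = np.exp(log_obs - shift[:, None])
    alpha = np.empty((T, C))
    scale = np.empty(T)
    a = pi * B[0]
    scale[0] = a.sum()
    if scale[0] <= 0:
        raise FloatingPointError("sequence has zero probability under the model")
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        scale[t] = a.sum()
        if scale[t] <= 0:
            raise FloatingPointError("sequence has zero probability under the model")
        alpha[t] = a / scale[t]
    ll = float(np.log(scale).sum() + shift.sum())
    beta = np.empty((T, C))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((C, C))
    steps = []
    for t in range(T - 1):
        step = (alpha[t][:, None] * A) * (B[t + 1] * beta[t + 1])[None, :] / scale[t + 1]
        xi_sum += step
        if keep_steps:
            steps.append(step)
    return gamma, xi_sum, ll, (np.array(steps) if keep_steps else None)


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@dataclass
class FeatureScaler:
    """Per-feature z-scoring fitted on the training bird; stored with results."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        return cls(X.mean(axis=0), std)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.std

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) * self.std + self.mean


# ---------------------------------------------------------------------------
# KL divergences and conjugate algebra
# ---------------------------------------------------------------------------

def _logdet(A):
    sign, val = np.linalg.slogdet(A)
    if sign <= 0:
        raise np.linalg.LinAlgError("matrix is not positive definite")
    return val


def _dirichlet_kl(u, v):
    """KL(Dir(u) || Dir(v)) for 1-d parameter vectors."""
    U, V = u.sum(), v.sum()
    return float(
        gammaln(U) - gammaln(u).sum() - gammaln(V) + gammaln(v).sum()
        + ((u - v) * (digamma(u) - digamma(U))).sum()
    )

def _e_log_det_lambda(W, nu):
    D = W.shape[0]
    return digamma(0.5 * (nu - np.arange(D))).sum() + D * np.log(2.0) + _logdet(W)


def _log_wishart_b(W, nu):
    D = W.shape[0]
    return (
        -0.5 * nu * _logdet(W)
        - 0.5 * nu * D * np.log(2.0)
        - 0.25 * D * (D - 1) * np.log(np.pi)
        - gammaln(0.5 * (nu - np.arange(D))).sum()
    )


def _normal_wishart_kl(m, beta, W, nu, m0, beta0, W0, nu0):
    """KL( NW(m,beta,W,nu) || NW(m0,beta0,W0,nu0) )."""
    D = len(m)
    elnlam = _e_log_det_lambda(W, nu)
    dm = m - m0
    kl_n = 0.5 * (
        D * np.log(beta / beta0) - D + D * beta0 / beta + beta0 * nu * dm @ W @ dm
    )
    e_ln_q_lam = _log_wishart_b(W, nu) + 0.5 * (nu - D - 1) * elnlam - 0.5 * nu * D
    e_ln_p_lam = (
        _log_wishart_b(W0, nu0)
        + 0.5 * (nu0 - D - 1) * elnlam
        - 0.5 * nu * np.trace(np.linalg.inv(W0) @ W)
    )
    return float(kl_n + e_ln_q_lam - e_ln_p_lam)


def gaussian_marginal_loglik(X: np.ndarray, hyper: VBHyperparams | None = None) -> float:
    """Exact log marginal likelihood of iid Gaussian data under the
    Normal–Wishart prior (single state, no mixture).

    With a conjugate prior the marginal is available in closed form as a
    ratio of Normal–Wishart normalizers; VB with K=1 attains this value at
    convergence, and bounds it from below at every iteration.
    """
    X = np.asarray(X, float)
    N, D = X.shape
    hyper = hyper or VBHyperparams()
    m0, beta0, W0, nu0 = hyper.resolve(X)

    def log_z(beta, W, nu):
        return (
            0.5 * D * np.log(2.0 * np.pi / beta)
            + 0.5 * nu * D * np.log(2.0)
            + gammaln(0.5 * (nu - np.arange(D))).sum()
            + 0.25 * D * (D - 1) * np.log(np.pi)
            + 0.5 * nu * _logdet(W)
        )

    xbar = X.mean(axis=0)
    S = (X - xbar).T @ (X - xbar)
    beta_n = beta0 + N
    nu_n = nu0 + N
    m_n = (beta0 * m0 + N * xbar) / beta_n
    dm = xbar - m0
    W_n = np.linalg.inv(np.linalg.inv(W0) + S + (beta0 * N / beta_n) * np.outer(dm, dm))
    return float(-0.5 * N * D * _LOG2PI + log_z(beta_n, W_n, nu_n) - log_z(beta0, W0, nu0))


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class VBPosterior:
    """Variational posterior: Dirichlet counts plus per-state Normal–Wishart."""

    u_pi: np.ndarray            # (K,) initial / mixture-weight Dirichlet
    u_A: np.ndarray | None      # (C, K) transition-row Dirichlets; None for order 0
    m: np.ndarray               # (K, D)
    beta: np.ndarray            # (K,)
    W: np.ndarray               # (K, D, D)
    nu: np.ndarray              # (K,)

    def expected_log_pi(self):
        return digamma(self.u_pi) - digamma(self.u_pi.sum())

    def expected_log_A(self):
        return digamma(self.u_A) - digamma(self.u_A.sum(axis=1))[:, None]

    def expected_log_emissions(self, X: np.ndarray) -> np.ndarray:
        """(T, K) expected Gaussian log densities under q(mean, precision)."""
        T, D = X.shape
        K = len(self.u_pi)
        out = np.empty((T, K))
        for k in range(K):
            elnlam = _e_log_det_lambda(self.W[k], self.nu[k])
            diff = X - self.m[k]
            quad = np.einsum("ti,ij,tj->t", diff, self.W[k], diff)
            out[:, k] = 0.5 * (elnlam - D * _LOG2PI - D / self.beta[k] - self.nu[k] * quad)
        return out

    def mean_params(self):
        """Posterior-mean parameters for plug-in prediction and decoding."""
        pi = self.u_pi / self.u_pi.sum()
        A = None if self.u_A is None else self.u_A / self.u_A.sum(axis=1, keepdims=True)
        precisions = self.nu[:, None, None] * self.W
        return pi, A, self.m.copy(), precisions

    def to_dict(self):
        return {
            "u_pi": self.u_pi.tolist(),
            "u_A": None if self.u_A is None else self.u_A.tolist(),
            "m": self.m.tolist(),
            "beta": self.beta.tolist(),
            "W": self.W.tolist(),
            "nu": self.nu.tolist(),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            np.array(d["u_pi"]),
            None if d["u_A"] is None else np.array(d["u_A"]),
            np.array(d["m"]),
            np.array(d["beta"]),
            np.array(d["W"]),
            np.array(d["nu"]),
        )


def _gaussian_logpdf(X, mean, precision):
    diff = X - mean
    quad = np.einsum("ti,ij,tj->t", diff, precision, diff)
    return 0.5 * (_logdet(precision) - FEATURE_DIM * _LOG2PI - quad)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class GaussianHMM:
    """Order-r Gaussian-emission HMM over per-syllable acoustic features.

    Parameters
    ----------
    data
        Training bouts (:class:`~songhmm.pomm.SongDataset`).
    order
        Markov order of the hidden chain: 0 (Gaussian mixture), 1, or 2.
    n_states
        Number of hidden states K.  With K larger than the number of
        syllable types (*redundant states*) a first-order chain can emit
        label sequences with second-order dependency.
    hyper
        Prior settings; defaults are weakly informative (see
        :class:`VBHyperparams`).
    scale
        z-score features on this dataset before fitting (the scaler is kept
        on the results so held-out data is mapped identically).
    """

    def __init__(self, data: SongDataset, order: int, n_states: int,
                 hyper: VBHyperparams | None = None, scale: bool = True):
        if order not in (0, 1, 2):
            raise ValueError("order must be 0, 1 or 2")
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        if len(data) == 0:
            raise ValueError("training dataset is empty")
        self.data = data
        self.order = int(order)
        self.n_states = int(n_states)
        self.hyper = hyper or VBHyperparams()
        stacked = data.stacked_features()
        self.scaler = FeatureScaler.fit(stacked) if scale else FeatureScaler(
            np.zeros(stacked.shape[1]), np.ones(stacked.shape[1])
        )
        self._X = [self.scaler.transform(b.features) for b in data.bouts]
        self._stacked = np.concatenate(self._X, axis=0)
        self._prior = self.hyper.resolve(self._stacked)
        self.ctx = expand_context(order, n_states) if order else None

    @classmethod
    def from_feature_table(cls, path, order, n_states, **kwargs):
        from .pomm import read_feature_table

        return cls(read_feature_table(path), order, n_states, **kwargs)

    # -- fitting ---------------------------------------------------------

    def fit(self, seed: int = 0, tol: float = 1e-6, max_iter: int = 500,
            n_restarts: int = 5, init_resp: np.ndarray | None = None) -> "VBHMMResults":
        """Run VB coordinate ascent from ``n_restarts`` seeded initializations.

        Returns the restart with the largest final lower bound.  If
        ``init_resp`` (stacked (N, K) responsibilities) is given, a single
        run starts from it instead of k-means seeding.
        """
        if tol <= 0:
            raise ValueError("tol must be positive")
        best = None
        restarts = 1 if init_resp is not None else max(1, int(n_restarts))
        for r in range(restarts):
            resp = (
                init_resp
                if init_resp is not None
                else self._init_responsibilities(seed + r, use_context=bool(r % 2))
            )
            result = self._fit_once(resp, seed=seed + r, tol=tol, max_iter=max_iter)
            if best is None or result.lower_bound > best.lower_bound:
                best = result
        best.n_restarts_used = restarts
        return best

    def _init_responsibilities(self, seed: int, use_context: bool = False) -> np.ndarray:
        """Seed responsibilities from k-means.

        Plain k-means clusters syllables by their own features; the
        context-aware variant appends the (down-weighted) features of the
        neighboring syllables, so states that differ only in sequential
        context start out separated.  Restarts alternate between the two.
        """
        N = len(self._stacked)
        K = self.n_states
        rng = np.random.default_rng(seed)
        if use_context and self.order > 0:
            blocks = []
            for X in self._X:
                prev = np.vstack([X[:1], X[:-1]])
                nxt = np.vstack([X[1:], X[-1:]])
                blocks.append(np.hstack([X, 0.5 * prev, 0.5 * nxt]))
            feats = np.concatenate(blocks, axis=0)
        else:
            feats = self._stacked
        if N >= K and len(np.unique(feats, axis=0)) >= K:
            km = KMeans(n_clusters=K, n_init=1, random_state=int(seed) % (2**31), max_iter=50)
            hard = km.fit_predict(feats)
        else:
            hard = rng.integers(0, K, size=N)
        resp = np.full((N, K), 0.1 / K)
        resp[np.arange(N), hard] += 0.9
        return resp

    def _fit_once(self, resp, seed, tol, max_iter):
        post = self._m_step_from_resp(resp)
        trace = []
        converged = False
        empty_events = []
        for it in range(max_iter):
            bound, stats = self._e_step(post)
            trace.append(bound)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                converged = True
                break
            post = self._m_step(stats, empty_events)
        return VBHMMResults(
            model=self,
            posterior=post,
            free_energy_trace=trace,
            converged=converged,
            seed=seed,
            n_restarts_used=1,
            empty_state_events=empty_events,
        )

    # -- E step ----------------------------------------------------------

    def _e_step(self, post: VBPosterior):
        alpha0 = self.hyper.dirichlet_alpha0
        m0, beta0, W0, nu0 = self._prior
        K = self.n_states
        kl = _dirichlet_kl(post.u_pi, np.full(K, alpha0))
        if post.u_A is not None:
            for row in post.u_A:
                kl += _dirichlet_kl(row, np.full(K, alpha0))
        for k in range(K):
            kl += _normal_wishart_kl(post.m[k], post.beta[k], post.W[k], post.nu[k],
                                     m0, beta0, W0, nu0)

        ll_sum = 0.0
        if self.order == 0:
            eln_pi = post.expected_log_pi()
            N = len(self._stacked)
            gamma = np.empty((N, K))
            offset = 0
            for X in self._X:
                logr = eln_pi[None, :] + post.expected_log_emissions(X)
                norm = logsumexp(logr, axis=1)
                ll_sum += float(norm.sum())
                gamma[offset:offset + len(X)] = np.exp(logr - norm[:, None])
                offset += len(X)
            return ll_sum - kl, {"gamma_state": gamma, "first": None, "xi": None}

        ctx = self.ctx
        log_init = np.full(ctx.n_contexts, -np.inf)
        log_init[ctx.initial_context] = post.expected_log_pi()
        logM = ctx.expand_trans_matrix(post.expected_log_A())
        gam_blocks, xi_sum = [], np.zeros((ctx.n_contexts, ctx.n_contexts))
        first = np.zeros(K)
        for X in self._X:
            logB = post.expected_log_emissions(X)
            g, xs, ll, _ = _forward_backward(logB[:, ctx.cur_state], log_init, logM)
            ll_sum += ll
            xi_sum += xs
            gam_blocks.append(ctx.state_marginal(g))
            first += ctx.state_marginal(g[:1])[0]
        gamma = np.concatenate(gam_blocks, axis=0)
        xi = xi_sum[np.arange(ctx.n_contexts)[:, None], ctx.succ]  # (C, K) counts
        return ll_sum - kl, {"gamma_state": gamma, "first": first, "xi": xi}

    # -- M step ----------------------------------------------------------

    def _m_step(self, stats, empty_events=None):
        alpha0 = self.hyper.dirichlet_alpha0
        gamma = stats["gamma_state"]
        if self.order == 0:
            u_pi = alpha0 + gamma.sum(axis=0)
            u_A = None
        else:
            u_pi = alpha0 + stats["first"]
            u_A = alpha0 + stats["xi"]
        m, beta, W, nu = self._niw_update(gamma, empty_events)
        return VBPosterior(u_pi, u_A, m, beta, W, nu)

    def _m_step_from_resp(self, resp):
        """Initial M-step from stacked responsibilities (plus hard n-gram counts)."""
        alpha0 = self.hyper.dirichlet_alpha0
        K = self.n_states
        if self.order == 0:
            u_pi = alpha0 + resp.sum(axis=0)
            u_A = None
        else:
            hard = resp.argmax(axis=1)
            seqs, offset = [], 0
            for X in self._X:
                seqs.append(hard[offset:offset + len(X)])
                offset += len(X)
            first = np.zeros(K)
            xi = np.zeros((self.ctx.n_contexts, K))
            for z in seqs:
                first[z[0]] += 1
                if self.order == 1:
                    for a, b in zip(z, z[1:]):
                        xi[a, b] += 1
                else:
                    for t in range(1, len(z)):
                        prev2 = DUMMY if t < 2 else int(z[t - 2])
                        c = self.ctx.index[(prev2, int(z[t - 1]))]
                        xi[c, z[t]] += 1
            u_pi = alpha0 + first
            u_A = alpha0 + xi
        m, beta, W, nu = self._niw_update(resp, None)
        return VBPosterior(u_pi, u_A, m, beta, W, nu)

    def _niw_update(self, gamma, empty_events):
        m0, beta0, W0, nu0 = self._prior
        X = self._stacked
        K = self.n_states
        D = X.shape[1]
        Nk = gamma.sum(axis=0)
        m = np.empty((K, D))
        W = np.empty((K, D, D))
        beta = beta0 + Nk
        nu = nu0 + Nk
        W0_inv = np.linalg.inv(W0)
        for k in range(K):
            if Nk[k] < 1e-6:
                if empty_events is not None:
                    empty_events.append(k)
                    logger.info("state %d lost all responsibility; reverting to prior", k)
                xbar, S = m0, np.zeros((D, D))
            else:
                xbar = gamma[:, k] @ X / Nk[k]
                diff = X - xbar
                S = (gamma[:, k][:, None] * diff).T @ diff
            m[k] = (beta0 * m0 + Nk[k] * xbar) / beta[k]
            dm = xbar - m0
            W[k] = np.linalg.inv(W0_inv + S + (beta0 * Nk[k] / beta[k]) * np.outer(dm, dm))
        return m, beta, W, nu


def vb_fit(data: SongDataset, order: int, n_states: int,
           hyper: VBHyperparams | None = None, seed: int = 0, tol: float = 1e-6,
           max_iter: int = 500, n_restarts: int = 5, scale: bool = True) -> "VBHMMResults":
    """Convenience wrapper: construct :class:`GaussianHMM` and fit it."""
    return GaussianHMM(data, order, n_states, hyper=hyper, scale=scale).fit(
        seed=seed, tol=tol, max_iter=max_iter, n_restarts=n_restarts
    )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class PredictiveLogLik:
    """Plug-in log-likelihood on held-out bouts, total and per syllable."""

    total: float
    per_syllable: float
    n_syllables: int

    def __float__(self):
        return self.total


@dataclass
class VBHMMResults:
    """Fitted VB posterior plus diagnostics; produced by :meth:`GaussianHMM.fit`.

    ``free_energy_trace`` holds the variational lower bound L on the log
    marginal likelihood (the negative variational free energy) after each
    E-step; it is non-decreasing and its last entry, :attr:`lower_bound`, is
    the model-selection score.
    """

    model: GaussianHMM
    posterior: VBPosterior
    free_energy_trace: list
    converged: bool
    seed: int
    n_restarts_used: int
    empty_state_events: list = field(default_factory=list)

    @property
    def order(self):
        return self.model.order

    @property
    def n_states(self):
        return self.model.n_states

    @property
    def lower_bound(self) -> float:
        return self.free_energy_trace[-1]

    @property
    def scaler(self) -> FeatureScaler:
        return self.model.scaler

    # -- evaluation ------------------------------------------------------

    def expected_data_loglik(self, data: SongDataset) -> float:
        """Sum over bouts of the expected-parameter log normalizer.

        This is the data-dependent term of the lower bound; evaluating it on
        a dataset twice the size exactly doubles it, the KL penalty being
        data-independent.
        """
        post = self.posterior
        total = 0.0
        if self.order == 0:
            eln_pi = post.expected_log_pi()
            for b in data.bouts:
                X = self.scaler.transform(b.features)
                total += float(logsumexp(eln_pi[None, :] + post.expected_log_emissions(X), axis=1).sum())
            return total
        ctx = self.model.ctx
        log_init = np.full(ctx.n_contexts, -np.inf)
        log_init[ctx.initial_context] = post.expected_log_pi()
        logM = ctx.expand_trans_matrix(post.expected_log_A())
        for b in data.bouts:
            X = self.scaler.transform(b.features)
            logB = post.expected_log_emissions(X)
            _, _, ll, _ = _forward_backward(logB[:, ctx.cur_state], log_init, logM)
            total += ll
        return total

    def kl_penalty(self) -> float:
        """KL(q(parameters) || prior): the complexity term of the bound."""
        bound, _ = self.model._e_step(self.posterior)
        return self.expected_data_loglik(self.model.data) - bound

    def predictive_loglik(self, test: SongDataset) -> PredictiveLogLik:
        """Plug-in log-likelihood of held-out bouts at posterior-mean parameters.

        Means use E[mean]=m and E[precision]=nu*W; the forward pass uses the
        training scaler, so the value is comparable across model orders.
        """
        if len(test) == 0:
            raise ValueError("test dataset is empty")
        pi, A, means, precisions = self.posterior.mean_params()
        K = self.n_states
        total = 0.0
        n = 0
        for b in test.bouts:
            X = self.scaler.transform(b.features)
            logB = np.column_stack([_gaussian_logpdf(X, means[k], precisions[k]) for k in range(K)])
            n += len(X)
            if self.order == 0:
                total += float(logsumexp(np.log(pi)[None, :] + logB, axis=1).sum())
                continue
            ctx = self.model.ctx
            log_init = np.full(ctx.n_contexts, -np.inf)
            with np.errstate(divide="ignore"):
                log_init[ctx.initial_context] = np.log(pi)
                logM = ctx.expand_trans_matrix(np.log(A))
            _, _, ll, _ = _forward_backward(logB[:, ctx.cur_state], log_init, logM)
            total += ll
        return PredictiveLogLik(total, total / n, n)

    # -- decoding --------------------------------------------------------

    def state_posteriors(self, data: SongDataset) -> list:
        """Per-bout (T, K) marginal state posteriors (Baum-Welch gammas).

        For order 2 the context posteriors are summed over contexts sharing
        the same current state.
        """
        post = self.posterior
        out = []
        if self.order == 0:
            eln_pi = post.expected_log_pi()
            for b in data.bouts:
                X = self.scaler.transform(b.features)
                logr = eln_pi[None, :] + post.expected_log_emissions(X)
                out.append(np.exp(logr - logsumexp(logr, axis=1)[:, None]))
            return out
        ctx = self.model.ctx
        log_init = np.full(ctx.n_contexts, -np.inf)
        log_init[ctx.initial_context] = post.expected_log_pi()
        logM = ctx.expand_trans_matrix(post.expected_log_A())
        for b in data.bouts:
            X = self.scaler.transform(b.features)
            logB = post.expected_log_emissions(X)
            g, _, _, _ = _forward_backward(logB[:, ctx.cur_state], log_init, logM)
            out.append(ctx.state_marginal(g))
        return out

    def decode(self, data: SongDataset, method: str = "posterior") -> list:
        """Per-bout hidden state sequences.

        ``method="posterior"`` (default) takes, per syllable, the state with
        the highest marginal posterior; ``method="viterbi"`` returns the
        jointly most probable path under posterior-mean parameters.
        """
        if method == "posterior":
            return [g.argmax(axis=1).tolist() for g in self.state_posteriors(data)]
        if method == "viterbi":
            return [self._viterbi(b) for b in data.bouts]
        raise ValueError("method must be 'posterior' or 'viterbi'")

    def _viterbi(self, bout):
        pi, A, means, precisions = self.posterior.mean_params()
        X = self.scaler.transform(bout.features)
        K = self.n_states
        logB = np.column_stack([_gaussian_logpdf(X, means[k], precisions[k]) for k in range(K)])
        if self.order == 0:
            return (np.log(pi)[None, :] + logB).argmax(axis=1).tolist()
        ctx = self.model.ctx
        with np.errstate(divide="ignore"):
            log_init = np.full(ctx.n_contexts, -np.inf)
            log_init[ctx.initial_context] = np.log(pi)
            logM = ctx.expand_trans_matrix(np.log(A))
        T = len(X)
        obs = logB[:, ctx.cur_state]
        delta = log_init + obs[0]
        back = np.zeros((T, ctx.n_contexts), dtype=int)
        for t in range(1, T):
            scores = delta[:, None] + logM
            back[t] = scores.argmax(axis=0)
            delta = scores.max(axis=0) + obs[t]
        path = [int(delta.argmax())]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        path.reverse()
        return [int(ctx.cur_state[c]) for c in path]

    # -- bookkeeping -----------------------------------------------------

    def permute_states(self, perm) -> "VBHMMResults":
        """Results with hidden-state indices relabeled by ``perm`` (new = perm[old]).

        Relabeling is a symmetry of the model: the lower bound and the
        emitted annotations (after alignment) are unchanged.
        """
        perm = np.asarray(perm, int)
        K = self.n_states
        inv = np.empty(K, int)
        inv[perm] = np.arange(K)
        p = self.posterior
        if p.u_A is None:
            u_A = None
        else:
            ctx = self.model.ctx
            def map_ctx(c):
                return tuple(DUMMY if s == DUMMY else int(perm[s]) for s in c)
            cperm = np.array([ctx.index[map_ctx(c)] for c in ctx.contexts])
            u_A = np.empty_like(p.u_A)
            u_A[cperm[:, None], perm[None, :]] = p.u_A
        post = VBPosterior(
            u_pi=p.u_pi[inv], u_A=u_A, m=p.m[inv], beta=p.beta[inv], W=p.W[inv], nu=p.nu[inv]
        )
        return VBHMMResults(self.model, post, list(self.free_energy_trace), self.converged,
                            self.seed, self.n_restarts_used, list(self.empty_state_events))

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-style text block)."""
        pi, A, means, _ = self.posterior.mean_params()
        occ = self.posterior.nu - self.model._prior[3]
        lines = [
            "Gaussian HMM (Variational Bayes)".center(58),
            "=" * 58,
            f"order (Markov)      {self.order:>6d}    states (K)   {self.n_states:>8d}",
            f"bouts               {len(self.model.data):>6d}    syllables    {self.model.data.n_syllables:>8d}",
            f"lower bound L       {self.lower_bound:>14.3f}",
            f"iterations          {len(self.free_energy_trace):>6d}    converged    {str(self.converged):>8s}",
            f"restarts            {self.n_restarts_used:>6d}    seed         {self.seed:>8d}",
            "-" * 58,
            "state   occupancy   mean(duration, pitch, entropy)",
        ]
        for k in np.argsort(-occ):
            mu = self.scaler.inverse_transform(means[k])
            lines.append(
                f"{k:>5d}   {occ[k]:>9.1f}   ({mu[0]:8.1f}, {mu[1]:8.1f}, {mu[2]:7.3f})"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------

    def to_json(self, path) -> None:
        obj = {
            "order": self.order,
            "n_states": self.n_states,
            "hyper": self.model.hyper.to_dict(),
            "posterior": self.posterior.to_dict(),
            "free_energy_trace": [float(x) for x in self.free_energy_trace],
            "converged": self.converged,
            "seed": self.seed,
            "n_restarts_used": self.n_restarts_used,
            "scaler": {"mean": self.scaler.mean.tolist(), "std": self.scaler.std.tolist()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)
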