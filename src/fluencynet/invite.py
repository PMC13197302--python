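"""Gradient-based transition-model estimation (INVITE and INVITE-CN).

INVITE parameterizes the transition matrix through an unconstrained matrix
``beta`` mapped row-wise by a softmax, and minimizes the penalized negative
censored-random-walk log-likelihood

    min_beta  - sum_lists sum_transitions log P(next | prefix; beta)
               + (C_beta / 2) * sum_{i != j} beta_ij^2 .

The L2 term is a smoothing device: it pulls rows toward uniformity in the
absence of evidence rather than sparsifying.  INVITE-CN restricts the
optimizable entries to the support of a conceptual-network mask and
additionally optimizes per-node jump probabilities (logit scale) and the
landing distribution (softmax), with the first-word term included since the
walk starts at the jump state.

Gradients of the absorption probabilities are computed exactly via the
adjoint of each transient-block solve: with ``x = (I-Q)^{-1} r`` and
``y = (I-Q)^{-T} e_start``, the derivative of the absorption probability with
respect to a transient-to-transient entry is ``y_u x_v`` and with respect to
the target column ``y_u``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .corpus import Corpus
from .markov import TransitionModel

__all__ = ["OptimizerConfig", "InviteFit", "fit_invite", "fit_invite_cn"]


@dataclass(frozen=True)
class OptimizerConfig:
    method: str = "lbfgs"  # "lbfgs" (full-batch quasi-Newton) or "asgd"
    max_epochs: int = 500
    learning_rate: float = 0.5
    tol: float = 1e-9
    seed: int = 0
    init: str = "zeros"  # "zeros" (uniform rows) or "random"


@dataclass(frozen=True)
class InviteFit:
    model: TransitionModel
    objective: float
    grad_norm: float
    n_params: int


def _transitions(corpus: Corpus):
    """Yield (prefix_ids, target_id) for every within-list transition."""
    for fl in corpus.lists:
        for k in range(fl.length - 1):
            yield fl.words[: k + 1], fl.words[k + 1]


def _crw_logprob_and_grad(P: np.ndarray, transient: np.ndarray, start: int,
                          target: int, G: np.ndarray) -> float:
    """Log absorption probability at `target` from `start`, with the gradient
    w.r.t. entries of ``P`` accumulated into ``G`` (rows = transient states).

    ``transient`` indexes the transient block of ``P``; ``start`` is a
    position within ``transient``; ``target`` is a column of ``P``.
    """
    Q = P[np.ix_(transient, transient)]
    r = P[transient, target]
    n = len(transient)
    A = np.eye(n) - Q
    x = np.linalg.solve(A, r)
    e = np.zeros(n)
    e[start] = 1.0
    y = np.linalg.solve(A.T, e)
    prob = float(x[start])
    if prob <= 0:
        return -np.inf
    inv = 1.0 / prob
    G[np.ix_(transient, transient)] += inv * np.outer(y, x)
    G[transient, target] += inv * y
    return float(np.log(prob))


def _softmax_rows(beta: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Row-wise softmax restricted to a boolean support mask (off-support 0)."""
    masked = np.where(support, beta, -np.inf)
    out = np.zeros_like(beta)
    rows = support.any(axis=1)
    out[rows] = special.softmax(masked[rows], axis=1)
    return out


def _softmax_backprop(S: np.ndarray, dS: np.ndarray) -> np.ndarray:
    """Gradient through a row softmax: dbeta = S * (dS - rowsum(dS * S))."""
    inner = (dS * S).sum(axis=1, keepdims=True)
    return S * (dS - inner)


def _run_optimizer(fun, x0: np.ndarray, cfg: OptimizerConfig,
                   fun_list=None, n_lists: int = 0) -> np.ndarray:
    if cfg.method == "lbfgs":
        res = optimize.minimize(
            fun, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": cfg.max_epochs * 10, "ftol": cfg.tol, "gtol": 1e-8},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError("INVITE objective diverged (non-finite)")
        return res.x
    if cfg.method == "asgd":
        rng = np.random.default_rng(cfg.seed)
        x = x0.copy()
        avg = x0.copy()
        n_steps = 0
        prev_obj = np.inf
        for epoch in range(cfg.max_epochs):
            for li in rng.permutation(n_lists):
                _, g = fun_list(x, int(li))
                x -= cfg.learning_rate / (1.0 + 0.02 * n_steps) * g
                n_steps += 1
                avg += (x - avg) / n_steps
            obj, _ = fun(avg)
            if not np.isfinite(obj):
                raise RuntimeError("INVITE objective diverged (non-finite)")
            if abs(prev_obj - obj) < cfg.tol * (1.0 + abs(obj)):
                break
            prev_obj = obj
        return avg
    raise ValueError(f"unknown optimizer method {cfg.method!r}")


# ---------------------------------------------------------------------------
# INVITE (no jump state)


def invite_objective(
    beta_flat: np.ndarray, corpus: Corpus, c_beta: float, support: np.ndarray,
    lists: list[int] | None = None,
) -> tuple[float, np.ndarray]:
    """Penalized NLL of the CRW transitions and its gradient w.r.t. beta."""
    W = support.shape[0]
    beta = beta_flat.reshape(W, W)
    P = _softmax_rows(beta, support)
    G = np.zeros((W, W))
    nll = 0.0
    source = corpus.lists if lists is None else [corpus.lists[i] for i in lists]
    for fl in source:
        for k in range(fl.length - 1):
            prefix = np.asarray(fl.words[: k + 1], dtype=np.int64)
            lp = _crw_logprob_and_grad(P, prefix, k, fl.words[k + 1], G)
            if not np.isfinite(lp):
                return np.inf, np.zeros_like(beta_flat)
            nll -= lp
    dbeta = -_softmax_backprop(P, G)
    dbeta[~support] = 0.0
    obj = nll + 0.5 * c_beta * float((beta[support] ** 2).sum())
    dbeta[support] += c_beta * beta[support]
    return obj, dbeta.ravel()


def fit_invite(
    corpus: Corpus,
    c_beta: float = 0.0,
    optimizer: OptimizerConfig | None = None,
) -> InviteFit:
    """Fit the INVITE model: a full softmax transition matrix, no jump state.

    The returned model has ``theta = 0``; its landing slot carries the
    empirical word-frequency distribution, which is also the start
    distribution the likelihood of whole lists should use (start policy
    ``"frequency"``).
    """
    cfg = optimizer or OptimizerConfig()
    W = corpus.vocabulary.size
    if W < 2:
        raise ValueError("need at least two words")
    support = ~np.eye(W, dtype=bool)
    rng = np.random.default_rng(cfg.seed)
    beta0 = (rng.normal(0, 0.1, (W, W)) if cfg.init == "random" else np.zeros((W, W)))
    beta0[~support] = 0.0

    def fun(x):
        return invite_objective(x, corpus, c_beta, support)

    def fun_list(x, li):
        # per-list stochastic gradient: spread the L2 penalty over the lists
        return invite_objective(x, corpus, c_beta / corpus.n_lists, support, lists=[li])

    x = _run_optimizer(fun, beta0.ravel(), cfg, fun_list, corpus.n_lists)
    obj, grad = fun(x)
    P = _softmax_rows(x.reshape(W, W), support)
    freq = corpus.vocabulary.list_frequency.astype(float)
    model = TransitionModel(P, np.zeros(W), freq / freq.sum(), corpus.vocabulary.tokens)
    return InviteFit(model, float(obj), float(np.linalg.norm(grad)), W * (W - 1))


# ---------------------------------------------------------------------------
# INVITE-CN (masked beta + jump parameters)


def _unpack_cn(x: np.ndarray, W: int, n_beta: int, support: np.ndarray):
    beta_vals = x[:n_beta]
    t = x[n_beta:n_beta + W]
    u = x[n_beta + W:]
    beta = np.zeros((W, W))
    beta[support] = beta_vals
    return beta, t, u


def invite_cn_objective(
    x: np.ndarray, corpus: Corpus, c_beta: float, support: np.ndarray,
    lists: list[int] | None = None,
) -> tuple[float, np.ndarray]:
    """Penalized NLL (first-word term included) and gradient for INVITE-CN.

    Parameters: masked beta entries, per-node jump logits ``t`` and landing
    softmax weights ``u``.  Rows with empty mask support are forced to
    ``theta = 1`` and contribute no beta or theta gradient.
    """
    W = support.shape[0]
    n_beta = int(support.sum())
    beta, t, u = _unpack_cn(x, W, n_beta, support)
    has_row = support.any(axis=1)
    theta = special.expit(t)
    theta = np.where(has_row, theta, 1.0)
    S = _softmax_rows(beta, support)
    rho = special.softmax(u)
    full = np.zeros((W + 1, W + 1))
    full[0, 1:] = rho
    full[1:, 0] = theta
    full[1:, 1:] = (1.0 - theta)[:, None] * S

    G = np.zeros((W + 1, W + 1))
    nll = 0.0
    source = corpus.lists if lists is None else [corpus.lists[i] for i in lists]
    for fl in source:
        for k in range(fl.length):  # k = 0 is the first-word emission from jump
            transient = np.concatenate(([0], np.asarray(fl.words[:k], np.int64) + 1))
            start = len(transient) - 1 if k else 0
            lp = _crw_logprob_and_grad(full, transient, start, fl.words[k] + 1, G)
            if not np.isfinite(lp):
                return np.inf, np.zeros_like(x)
            nll -= lp

    # chain rule back to the free parameters (loss = nll, so negate G-paths)
    G_local = G[1:, 1:]
    dS = (1.0 - theta)[:, None] * G_local
    dbeta = _softmax_backprop(S, dS)
    dbeta[~support] = 0.0
    dtheta = G[1:, 0] - (G_local * S).sum(axis=1)
    dt = dtheta * theta * (1.0 - theta)
    dt[~has_row] = 0.0
    du = _softmax_backprop(rho[None, :], G[0, 1:][None, :])[0]

    beta_v = beta[support]
    obj = nll + 0.5 * c_beta * float((beta_v**2).sum())
    grad = np.concatenate([-dbeta[support] + c_beta * beta_v, -dt, -du])
    return obj, grad


def fit_invite_cn(
    corpus: Corpus,
    cn_mask: np.ndarray,
    c_beta: float = 0.0,
    optimizer: OptimizerConfig | None = None,
) -> InviteFit:
    """Fit INVITE-CN: masked softmax rows plus optimized jump and landing
    distributions.  Free parameter count is ``nnz(mask) + 2W - 1``, the
    number reported for BIC."""
    cfg = optimizer or OptimizerConfig()
    W = corpus.vocabulary.size
    mask = np.asarray(cn_mask, dtype=bool).copy()
    np.fill_diagonal(mask, False)
    n_beta = int(mask.sum())
    rng = np.random.default_rng(cfg.seed)
    if cfg.init == "random":
        x0 = np.concatenate([rng.normal(0, 0.1, n_beta), np.zeros(W), np.zeros(W)])
    else:
        x0 = np.zeros(n_beta + 2 * W)

    def fun(x):
        return invite_cn_objective(x, corpus, c_beta, mask)

    def fun_list(x, li):
        return invite_cn_objective(x, corpus, c_beta / corpus.n_lists, mask, lists=[li])

    x = _run_optimizer(fun, x0, cfg, fun_list, corpus.n_lists)
    obj, grad = fun(x)
    beta, t, u = _unpack_cn(x, W, n_beta, mask)
    has_row = mask.any(axis=1)
    theta = np.where(has_row, special.expit(t), 1.0)
    S = _softmax_rows(beta, mask)
    rho = special.softmax(u)
    model = TransitionModel((1.0 - theta)[:, None] * S, theta, rho,
                            corpus.vocabulary.tokens)
    return InviteFit(model, float(obj), float(np.linalg.norm(grad)),
                     n_beta + 2 * W - 1)
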