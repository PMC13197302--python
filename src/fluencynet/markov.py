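"""Jump-augmented transition models and censored-random-walk likelihoods.

The semantic network is a nonnegative weighted adjacency matrix ``A`` over
``W`` word nodes.  Row normalization turns it into a transition probability
matrix; a *jump pseudo-state* (global reset) is attached as state 0 of a
``(W+1) x (W+1)`` row-stochastic matrix whose first row is the landing
distribution ``rho`` and whose first column holds the per-node jump
probabilities ``theta``.

A *censored random walk* (CRW) emits a node only on first visit; revisits
traverse silently.  The probability of the next emitted word given a visited
prefix is the absorption probability of a walk in which the prefix (plus the
jump state, which is always transient) is transient and every unvisited word
is absorbing — a small linear solve per transition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .corpus import Corpus, FluencyList

__all__ = [
    "AdjacencyMatrix",
    "JumpWeights",
    "TransitionModel",
    "ReabsorbedModel",
    "row_normalize",
    "attach_jump_tpm",
    "attach_jump_adjacency",
    "reabsorb",
    "crw_transition_prob",
    "crw_transition_dist",
    "list_loglik",
    "corpus_loglik",
    "corpus_gll",
    "adjusted_jump_probability",
]

_ROW_TOL = 1e-9

StartPolicy = Literal["jump", "frequency"]


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Nonnegative W x W weight table; zero diagonal."""

    weights: np.ndarray
    directed: bool = False
    weighted: bool = True

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if (w < 0).any():
            raise ValueError("adjacency weights must be nonnegative")
        if np.abs(np.diag(w)).max(initial=0.0) > 0:
            raise ValueError("adjacency diagonal must be zero")
        if not self.directed and not np.allclose(w, w.T):
            raise ValueError("undirected adjacency must be symmetric")
        if not self.weighted and not np.isin(w[w > 0], [1.0]).all():
            raise ValueError("unweighted adjacency must be 0/1")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def binarized(self) -> np.ndarray:
        return (self.weights > 0).astype(float)


@dataclass(frozen=True)
class JumpWeights:
    """Unnormalized node->jump weights (theta~) and landing weights (rho~)."""

    theta_weights: np.ndarray
    landing_weights: np.ndarray

    def __post_init__(self) -> None:
        th = np.asarray(self.theta_weights, dtype=float)
        rh = np.asarray(self.landing_weights, dtype=float)
        object.__setattr__(self, "theta_weights", th)
        object.__setattr__(self, "landing_weights", rh)
        if th.shape != rh.shape or th.ndim != 1:
            raise ValueError("theta and landing weights must be 1-D and aligned")
        if (th < 0).any() or (rh < 0).any():
            raise ValueError("jump weights must be nonnegative")
        if th.sum() > 0 and rh.sum() == 0:
            raise ValueError("positive jump weight with no landing mass")


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic (W+1) x (W+1) matrix with the jump state at index 0.

    ``local`` is the W x W semantic block (row ``i`` sums to ``1 - theta[i]``),
    ``theta`` the per-node jump probabilities, ``rho`` the landing
    distribution.  Semantic ids are 0-based externally; internally they live
    at indices ``1..W`` of ``full``.
    """

    local: np.ndarray
    theta: np.ndarray
    rho: np.ndarray
    tokens: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        local = np.asarray(self.local, dtype=float)
        theta = np.asarray(self.theta, dtype=float)
        rho = np.asarray(self.rho, dtype=float)
        for name, val in (("local", local), ("theta", theta), ("rho", rho)):
            object.__setattr__(self, name, val)
        W = local.shape[0]
        if local.shape != (W, W) or theta.shape != (W,) or rho.shape != (W,):
            raise ValueError("inconsistent model shapes")
        if (local < 0).any() or (theta < -1e-15).any() or (rho < 0).any():
            raise ValueError("negative probabilities")
        if np.abs(np.diag(local)).max(initial=0.0) > 0:
            raise ValueError("local diagonal must be zero")
        if abs(rho.sum() - 1.0) > _ROW_TOL:
            raise ValueError(f"rho sums to {rho.sum()!r}, not 1")
        row_sums = local.sum(axis=1) + theta
        if np.abs(row_sums - 1.0).max(initial=0.0) > _ROW_TOL:
            raise ValueError("local row + theta must sum to 1 per node")

    @property
    def n_words(self) -> int:
        return self.local.shape[0]

    @property
    def full(self) -> np.ndarray:
        """The (W+1) x (W+1) row-stochastic matrix, jump state at index 0."""
        cached = self.__dict__.get("_full_cache")
        if cached is None:
            W = self.n_words
            cached = np.zeros((W + 1, W + 1))
            cached[0, 1:] = self.rho
            cached[1:, 0] = self.theta
            cached[1:, 1:] = self.local
            self.__dict__["_full_cache"] = cached
        return cached

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        W = self.n_words
        rows, cols = np.nonzero(self.local)
        payload = {
            "n_words": W,
            "tokens": list(self.tokens) if self.tokens is not None else None,
            "local_triplets": [
                [int(r), int(c), float(self.local[r, c])] for r, c in zip(rows, cols)
            ],
            "theta": self.theta.tolist(),
            "rho": self.rho.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TransitionModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        W = payload["n_words"]
        local = np.zeros((W, W))
        for r, c, v in payload["local_triplets"]:
            local[r, c] = v
        tokens = payload.get("tokens")
        return cls(
            local,
            np.asarray(payload["theta"], dtype=float),
            np.asarray(payload["rho"], dtype=float),
            tuple(tokens) if tokens is not None else None,
        )

    def to_edge_list(self, path, node_path=None) -> None:
        """TSV export: edges ``source target weight``; optional node table with
        per-node jump probability theta_i and landing probability rho_i."""
        names = self.tokens or tuple(str(i) for i in range(self.n_words))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tweight\n")
            for r, c in zip(*np.nonzero(self.local)):
                fh.write(f"{names[r]}\t{names[c]}\t{self.local[r, c]:.10g}\n")
        if node_path is not None:
            with open(node_path, "w", encoding="utf-8") as fh:
                fh.write("node\ttheta\trho\n")
                for i, name in enumerate(names):
                    fh.write(f"{name}\t{self.theta[i]:.10g}\t{self.rho[i]:.10g}\n")


@dataclass(frozen=True)
class ReabsorbedModel:
    """W x W row-stochastic matrix with the jump state algebraically removed.

    ``p_abs = local + outer(theta, rho)``: marginalizing a single pass through
    the jump state adds ``theta_i * rho_j`` to every semantic transition.
    """

    p_abs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p_abs, dtype=float)
        object.__setattr__(self, "p_abs", p)
        if np.abs(p.sum(axis=1) - 1.0).max(initial=0.0) > _ROW_TOL:
            raise ValueError("reabsorbed rows must sum to 1")


# ---------------------------------------------------------------------------
# construction


def row_normalize(
    adjacency: AdjacencyMatrix | np.ndarray,
    isolated: Literal["error", "zero"] = "error",
) -> np.ndarray:
    """Normalize each row of an adjacency matrix to a probability distribution.

    Rows with no outgoing weight either raise (default) or are left as zero
    rows (``isolated="zero"``), to be completed later by a jump attachment
    that sends all of that node's mass to the jump state.
    """
    w = adjacency.weights if isinstance(adjacency, AdjacencyMatrix) else np.asarray(adjacency, float)
    sums = w.sum(axis=1)
    empty = np.flatnonzero(sums == 0)
    if len(empty) and isolated == "error":
        raise ValueError(f"nodes with no outgoing weight: {empty.tolist()}")
    out = np.zeros_like(w, dtype=float)
    nz = sums > 0
    out[nz] = w[nz] / sums[nz, None]
    return out


def attach_jump_tpm(
    p: np.ndarray,
    theta: float | np.ndarray,
    rho: np.ndarray,
    tokens: tuple[str, ...] | None = None,
) -> TransitionModel:
    """Attach a jump state to a row-stochastic matrix.

    Each semantic row is scaled by ``1 - theta_i`` and the freed mass becomes
    the node->jump probability; the jump row is the landing distribution.
    Zero rows of ``p`` (isolated nodes) are forced to ``theta_i = 1``.
    """
    p = np.asarray(p, dtype=float)
    W = p.shape[0]
    rho = np.asarray(rho, dtype=float)
    if abs(rho.sum() - 1.0) > _ROW_TOL:
        raise ValueError(f"rho must sum to 1 (got {rho.sum()})")
    theta = np.full(W, float(theta)) if np.isscalar(theta) else np.asarray(theta, float).copy()
    if ((theta < 0) | (theta > 1)).any():
        raise ValueError("theta values must lie in [0, 1]")
    zero_rows = p.sum(axis=1) < _ROW_TOL
    theta[zero_rows] = 1.0
    local = (1.0 - theta)[:, None] * p
    return TransitionModel(local, theta, rho, tokens)


def attach_jump_adjacency(
    adjacency: AdjacencyMatrix,
    jump: JumpWeights,
    tokens: tuple[str, ...] | None = None,
) -> TransitionModel:
    """Border the adjacency with jump weights, then row-normalize.

    ``A' = [[0, rho~], [theta~, A]]``; row normalization of the bordered
    matrix gives ``theta_i = theta~_i / (theta~_i + sum_j a_ij)``.
    """
    a = adjacency.weights
    th, rh = jump.theta_weights, jump.landing_weights
    if rh.sum() <= 0:
        raise ValueError("landing weights must have positive total mass")
    out_mass = a.sum(axis=1) + th
    dead = np.flatnonzero(out_mass == 0)
    if len(dead):
        raise ValueError(f"nodes with zero row and zero jump weight: {dead.tolist()}")
    theta = th / out_mass
    local = a / out_mass[:, None]
    rho = rh / rh.sum()
    return TransitionModel(local, theta, rho, tokens)


def reabsorb(model: TransitionModel) -> ReabsorbedModel:
    return ReabsorbedModel(model.local + np.outer(model.theta, model.rho))


# ---------------------------------------------------------------------------
# censored-walk absorption probabilities

JUMP = 0  # index of the jump state in `full`


def _transient_indices(visited: Sequence[int]) -> np.ndarray:
    """Visited semantic ids plus the always-transient jump state, in `full`
    coordinates."""
    return np.concatenate(([JUMP], np.asarray(visited, dtype=np.int64) + 1))


def crw_transition_dist(model: TransitionModel, visited: Sequence[int]) -> np.ndarray:
    """Absorption distribution over *all* words given a visited prefix.

    Entry ``j`` is the probability the next emitted word is ``j`` (0 for
    already-visited words).  Computed by one dense solve of
    ``(I - Q)^T y = e_start`` over the transient block, then ``y @ R``.
    """
    visited = list(visited)
    if not visited:
        raise ValueError("visited prefix must be nonempty")
    if len(set(visited)) != len(visited):
        raise ValueError("visited prefix contains duplicates")
    full = model.full
    t_idx = _transient_indices(visited)
    mask = np.zeros(full.shape[0], dtype=bool)
    mask[t_idx] = True
    a_idx = np.flatnonzero(~mask)  # absorbing word states
    Q = full[np.ix_(t_idx, t_idx)]
    R = full[np.ix_(t_idx, a_idx)]
    start_pos = len(t_idx) - 1  # last visited node is appended last
    e = np.zeros(len(t_idx))
    e[start_pos] = 1.0
    try:
        y = np.linalg.solve(np.eye(len(t_idx)) - Q.T, e)
    except np.linalg.LinAlgError:
        warnings.warn("singular transient block; absorbing states unreachable", stacklevel=2)
        return np.zeros(model.n_words)
    probs = y @ R
    out = np.zeros(model.n_words)
    out[a_idx - 1] = np.clip(probs, 0.0, 1.0)
    return out


def crw_transition_prob(
    model: TransitionModel, visited: Sequence[int], target: int
) -> float:
    """P(next emitted word = target | visited prefix) under the CRW."""
    if target in set(visited):
        raise ValueError("target already visited")
    if target < 0 or target >= model.n_words:
        raise ValueError("target must be a semantic node (use adjusted_jump_probability)")
    return float(crw_transition_dist(model, visited)[target])


def _first_word_logprob(
    model: TransitionModel,
    word: int,
    start: StartPolicy,
    start_dist: np.ndarray | None,
) -> float:
    if start == "jump":
        p = model.rho[word]
    elif start == "frequency":
        if start_dist is None:
            raise ValueError("start policy 'frequency' needs a start distribution")
        p = start_dist[word]
    else:
        raise ValueError(f"unknown start policy {start!r}")
    with np.errstate(divide="ignore"):
        return float(np.log(p)) if p > 0 else -np.inf


def list_loglik(
    model: TransitionModel,
    fl: FluencyList | Sequence[int],
    start: StartPolicy = "jump",
    start_dist: np.ndarray | None = None,
) -> float:
    """CRW log-likelihood of one list: first-word term plus one absorbing
    solve per transition.  Zero-probability transitions yield ``-inf``."""
    words = list(fl.words if isinstance(fl, FluencyList) else fl)
    total = _first_word_logprob(model, words[0], start, start_dist)
    if not np.isfinite(total):
        return -np.inf
    for k in range(len(words) - 1):
        p = crw_transition_prob(model, words[: k + 1], words[k + 1])
        if p <= 0:
            return -np.inf
        total += float(np.log(p))
    return total


def corpus_loglik(
    model: TransitionModel,
    corpus: Corpus,
    start: StartPolicy = "jump",
    start_dist: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Total CRW log-likelihood and the per-list vector."""
    lls = np.array(
        [list_loglik(model, fl, start, start_dist) for fl in corpus.lists]
    )
    return float(lls.sum()), lls


def corpus_gll(
    model: TransitionModel,
    corpus: Corpus,
    start: StartPolicy = "jump",
    start_dist: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Geometric-mean per-emission probability (gLL) of a corpus.

    Returns the pooled value ``exp(sum_i ll_i / sum_i lambda_i)`` — the
    emission count includes the first word of each list — together with the
    per-list geometric means used for distributional analysis.  Any list with
    an impossible transition drives the pooled value to 0 (it is flagged by a
    ``-inf`` in the per-list vector).
    """
    _, lls = corpus_loglik(model, corpus, start, start_dist)
    lengths = corpus.lengths
    per_list = np.where(np.isfinite(lls), np.exp(lls / lengths), 0.0)
    if not np.isfinite(lls).all():
        warnings.warn(
            f"{int((~np.isfinite(lls)).sum())} lists have zero likelihood; gLL = 0",
            stacklevel=2,
        )
        return 0.0, per_list
    return float(np.exp(lls.sum() / lengths.sum())), per_list


def adjusted_jump_probability(
    model: TransitionModel, visited: Sequence[int]
) -> tuple[float, float]:
    """Base vs prefix-adjusted probability that the next transition is a jump.

    ``base`` is the static node->jump probability of the last visited word.
    ``adjusted`` is the absorption probability at the jump state of a walk
    where the visited words are transient and the jump state plus all
    unvisited words absorb — jumps reached through already-visited neighbors
    count, so the adjusted value grows as a semantic patch is depleted.
    """
    visited = list(visited)
    if not visited:
        raise ValueError("visited prefix must be nonempty")
    base = float(model.theta[visited[-1]])
    full = model.full
    t_idx = np.asarray(visited, dtype=np.int64) + 1  # jump is absorbing here
    mask = np.zeros(full.shape[0], dtype=bool)
    mask[t_idx] = True
    a_idx = np.flatnonzero(~mask)
    Q = full[np.ix_(t_idx, t_idx)]
    R = full[np.ix_(t_idx, a_idx)]
    e = np.zeros(len(t_idx))
    e[len(t_idx) - 1] = 1.0
    y = np.linalg.solve(np.eye(len(t_idx)) - Q.T, e)
    probs = y @ R
    jump_pos = int(np.flatnonzero(a_idx == JUMP)[0])
    return base, float(np.clip(probs[jump_pos], 0.0, 1.0))
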