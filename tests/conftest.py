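"""Shared fixtures: tiny corpora, random jump models, and a Monte-Carlo
censored-walk oracle that is independent of the linear-algebra solver."""

from __future__ import annotations

import numpy as np
import pytest

from fluencynet import corpus_from_token_lists
from fluencynet.markov import TransitionModel, attach_jump_tpm, row_normalize


@pytest.fixture
def tiny_corpus():
    """Three short lists over five words."""
    return corpus_from_token_lists(
        {"p1": ["a", "b", "c"], "p2": ["b", "d", "a"], "p3": ["c", "a", "d", "e"]}
    )


@pytest.fixture
def star_model():
    """Unweighted star H-{X,Y,Z}; ids 0=H, 1=X, 2=Y, 3=Z; no jumps."""
    a = np.zeros((4, 4))
    a[0, 1:] = 1.0
    a[1:, 0] = 1.0
    return attach_jump_tpm(row_normalize(a), 0.0, np.full(4, 0.25))


def random_jump_model(rng: np.random.Generator, n: int = 6) -> TransitionModel:
    """Random dense weighted model with node-specific jumps."""
    a = rng.uniform(0.1, 1.0, (n, n))
    np.fill_diagonal(a, 0.0)
    theta = rng.uniform(0.05, 0.5, n)
    rho = rng.dirichlet(np.ones(n))
    return attach_jump_tpm(row_normalize(a), theta, rho)


def mc_next_word_freq(
    model: TransitionModel,
    visited: list[int],
    n_walks: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo frequency of the next emitted word after a visited prefix.

    Simulates censored walks step by step on the full matrix (jump state and
    visited words transient, everything else absorbing); this is the
    independent oracle for the absorbing-chain solver.
    """
    full = model.full
    transient = {0} | {v + 1 for v in visited}
    cum = np.cumsum(full, axis=1)
    state = np.full(n_walks, visited[-1] + 1)
    result = np.zeros(model.n_words)
    active = np.ones(n_walks, dtype=bool)
    while active.any():
        s = state[active]
        u = rng.random(s.size)
        nxt = np.empty_like(s)
        for st in np.unique(s):
            m = s == st
            nxt[m] = np.searchsorted(cum[st], u[m], side="right")
        idx = np.flatnonzero(active)
        done = np.array([x not in transient for x in nxt])
        for x in nxt[done]:
            result[x - 1] += 1
        state[idx] = nxt
        active[idx[done]] = False
    return result / n_walks
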