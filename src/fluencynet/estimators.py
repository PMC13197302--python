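"""Network estimators: from a training corpus to an adjacency matrix.

Unweighted methods (FE, NRW, Pathfinder, CN, CBN, U-INVITE) return binary
undirected networks and rely on an attached jump state with a tuned scalar
jump probability to make every transition possible.  Weighted methods
(BIGRAM-FIXED, BIGRAM-IND, BIGRAM-CN) count ordered adjacent word pairs;
the -IND and -CN variants pool pruned edge weight into per-node jump weights,
giving each word its own jump probability.
"""

from __future__ import annotations

import hashlib
import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .corpus import Corpus
from .markov import (
    AdjacencyMatrix,
    JumpWeights,
    TransitionModel,
    attach_jump_tpm,
    corpus_loglik,
    row_normalize,
)

__all__ = [
    "EstimatorConfig",
    "EstimatorResult",
    "estimate_fe",
    "estimate_nrw",
    "estimate_pathfinder",
    "estimate_cn",
    "estimate_cbn",
    "estimate_uinvite",
    "estimate_bigram_fixed",
    "estimate_bigram_ind",
    "estimate_bigram_cn",
    "cn_exceedance_probability",
    "to_transition_model",
    "CN_2_3",
]


@dataclass(frozen=True)
class EstimatorConfig:
    """Shared estimator knobs.

    window: maximum positional separation counted as a co-occurrence (CN).
    min_cooc: minimum number of co-occurring lists to admit a CN edge.
    alpha: significance level of the CN test (Bonferroni-corrected).
    gamma: bigram-count exponent of BIGRAM-CN (0 -> binary weights).
    prune_threshold: minimum bigram count kept by BIGRAM-IND.
    pf_q, pf_r: Pathfinder sparsity parameters (defaults give the sparsest
        network: q = W - 1, r = infinity).
    """

    window: int = 2
    min_cooc: int = 3
    alpha: float = 0.05
    gamma: float = 1.0
    prune_threshold: int = 4
    pf_q: int | None = None
    pf_r: float = np.inf

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_cooc < 1:
            raise ValueError("window and min_cooc must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


#: the named preset used throughout reporting: window 2, min co-occurrence 3.
CN_2_3 = EstimatorConfig(window=2, min_cooc=3)


@dataclass(frozen=True)
class EstimatorResult:
    adjacency: AdjacencyMatrix
    jump: JumpWeights | None = None
    provenance: dict = field(default_factory=dict)
    tokens: tuple[str, ...] | None = None


def _fingerprint(corpus: Corpus) -> str:
    h = hashlib.sha1()
    for fl in corpus.lists:
        h.update(fl.list_id.encode())
        h.update(np.asarray(fl.words, dtype=np.int64).tobytes())
    h.update("|".join(corpus.vocabulary.tokens).encode())
    return h.hexdigest()[:12]


def _prov(corpus: Corpus, method: str, **params) -> dict:
    return {"method": method, "corpus": _fingerprint(corpus), **params}


# ---------------------------------------------------------------------------
# unweighted methods


def estimate_fe(corpus: Corpus) -> EstimatorResult:
    """First-edge: one undirected edge per list, between its first two words."""
    W = corpus.vocabulary.size
    a = np.zeros((W, W))
    skipped = 0
    for fl in corpus.lists:
        if fl.length < 2:
            skipped += 1
            continue
        i, j = fl.words[0], fl.words[1]
        a[i, j] = a[j, i] = 1.0
    if skipped:
        warnings.warn(f"{skipped} single-word lists skipped by FE", stacklevel=2)
    return EstimatorResult(
        AdjacencyMatrix(a, directed=False, weighted=False),
        provenance=_prov(corpus, "fe"),
        tokens=corpus.vocabulary.tokens,
    )


def estimate_nrw(corpus: Corpus) -> EstimatorResult:
    """Naive random walk: an undirected edge for every adjacent word pair."""
    W = corpus.vocabulary.size
    a = np.zeros((W, W))
    for fl in corpus.lists:
        for i, j in zip(fl.words, fl.words[1:]):
            a[i, j] = a[j, i] = 1.0
    return EstimatorResult(
        AdjacencyMatrix(a, directed=False, weighted=False),
        provenance=_prov(corpus, "nrw"),
        tokens=corpus.vocabulary.tokens,
    )


def positional_distance_matrix(corpus: Corpus) -> np.ndarray:
    """Mean absolute positional separation per word pair; inf if never co-listed."""
    W = corpus.vocabulary.size
    total = np.zeros((W, W))
    count = np.zeros((W, W))
    for fl in corpus.lists:
        ids = np.asarray(fl.words)
        pos = np.arange(fl.length)
        sep = np.abs(pos[:, None] - pos[None, :]).astype(float)
        total[np.ix_(ids, ids)] += sep
        count[np.ix_(ids, ids)] += 1.0
    with np.errstate(invalid="ignore"):
        dist = np.where(count > 0, total / np.maximum(count, 1), np.inf)
    np.fill_diagonal(dist, np.inf)
    return dist


def _minimax_distances(dist: np.ndarray) -> np.ndarray:
    """All-pairs minimax (bottleneck) path distances by Floyd-Warshall."""
    m = dist.copy()
    n = m.shape[0]
    for k in range(n):
        via = np.maximum.outer(m[:, k], m[k, :])
        m = np.minimum(m, via)
    return m


def estimate_pathfinder(corpus: Corpus, config: EstimatorConfig | None = None) -> EstimatorResult:
    """Pathfinder sparsification of the positional-proximity matrix.

    With q = W - 1 and r = infinity (the sparsest setting) an edge survives
    iff its direct distance does not exceed the minimax path distance between
    its endpoints.
    """
    dist = positional_distance_matrix(corpus)
    if not np.isfinite(dist).any():
        warnings.warn("all pairwise distances infinite; empty network", stacklevel=2)
        W = corpus.vocabulary.size
        return EstimatorResult(
            AdjacencyMatrix(np.zeros((W, W)), weighted=False),
            provenance=_prov(corpus, "pf"),
            tokens=corpus.vocabulary.tokens,
        )
    minimax = _minimax_distances(dist)
    keep = np.isfinite(dist) & (dist <= minimax + 1e-12)
    a = keep.astype(float)
    a = np.maximum(a, a.T)  # distances are symmetric; guard numeric asymmetry
    np.fill_diagonal(a, 0.0)
    return EstimatorResult(
        AdjacencyMatrix(a, directed=False, weighted=False),
        provenance=_prov(corpus, "pf"),
        tokens=corpus.vocabulary.tokens,
    )


def _window_cooc_prob(length: int, window: int) -> float:
    """P(two tokens of a list land within `window` positions) under the null
    that their positions are a uniform random pair of the list's slots."""
    if length < 2:
        return 0.0
    d = min(window, length - 1)
    n_close = d * length - d * (d + 1) // 2
    n_pairs = length * (length - 1) // 2
    return n_close / n_pairs


def _poisson_binomial_sf(probs: np.ndarray, c: int) -> float:
    """P(X >= c) for X a sum of independent Bernoulli(probs): exact DP."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.concatenate((pmf * (1 - p), [0.0])) + np.concatenate(([0.0], pmf * p))
    return float(pmf[c:].sum())


def cn_exceedance_probability(
    lengths: np.ndarray, window: int, observed: int
) -> float:
    """Exceedance probability of an observed within-window co-occurrence count.

    ``lengths`` are the lengths of the lists containing both words; under the
    null each list contributes a Bernoulli trial with the closed-form
    within-window probability for its length.
    """
    probs = np.array([_window_cooc_prob(int(l), window) for l in lengths])
    return _poisson_binomial_sf(probs, observed)


def estimate_cn(corpus: Corpus, config: EstimatorConfig = CN_2_3) -> EstimatorResult:
    """Conceptual network: edges whose within-window co-occurrence count beats
    a random-placement null (Bonferroni over tested pairs) and a minimum
    count threshold."""
    W = corpus.vocabulary.size
    max_len = int(corpus.lengths.max(initial=0))
    if config.window >= max_len:
        warnings.warn("window >= max list length; saturates to whole-list co-occurrence",
                      stacklevel=2)
    close_count: dict[tuple[int, int], int] = {}
    both_lengths: dict[tuple[int, int], list[int]] = {}
    for fl in corpus.lists:
        ids = fl.words
        present_pairs = {tuple(sorted(p)) for p in itertools.combinations(ids, 2)}
        for pair in present_pairs:
            both_lengths.setdefault(pair, []).append(fl.length)
        for d in range(1, min(config.window, fl.length - 1) + 1):
            for i, j in zip(ids, ids[d:]):
                pair = (i, j) if i < j else (j, i)
                close_count[pair] = close_count.get(pair, 0) + 1
    tested = list(both_lengths)
    m = max(len(tested), 1)
    a = np.zeros((W, W))
    for pair in tested:
        c = close_count.get(pair, 0)
        if c < config.min_cooc:
            continue
        p = cn_exceedance_probability(np.array(both_lengths[pair]), config.window, c)
        if p * m < config.alpha:
            i, j = pair
            a[i, j] = a[j, i] = 1.0
    return EstimatorResult(
        AdjacencyMatrix(a, directed=False, weighted=False),
        provenance=_prov(corpus, "cn", window=config.window,
                         min_cooc=config.min_cooc, alpha=config.alpha),
        tokens=corpus.vocabulary.tokens,
    )


def estimate_cbn(corpus: Corpus) -> EstimatorResult:
    """Correlation-based network: rank word pairs by the Pearson correlation of
    their list-occurrence vectors and add edges greedily while the graph stays
    planar."""
    W = corpus.vocabulary.size
    N = corpus.n_lists
    occ = np.zeros((N, W))
    for li, fl in enumerate(corpus.lists):
        occ[li, list(fl.words)] = 1.0
    centered = occ - occ.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered.T @ centered) / np.outer(norms, norms)
    ranked = sorted(
        (
            (i, j, corr[i, j])
            for i, j in itertools.combinations(range(W), 2)
            if np.isfinite(corr[i, j])
        ),
        key=lambda t: (-t[2], t[0], t[1]),
    )
    g = nx.Graph()
    g.add_nodes_from(range(W))
    a = np.zeros((W, W))
    for i, j, _ in ranked:
        g.add_edge(i, j)
        if nx.check_planarity(g, counterexample=False)[0]:
            a[i, j] = a[j, i] = 1.0
        else:
            g.remove_edge(i, j)
        if g.number_of_edges() >= 3 * (W - 2):
            break  # maximal planar graph reached
    return EstimatorResult(
        AdjacencyMatrix(a, directed=False, weighted=False),
        provenance=_prov(corpus, "cbn"),
        tokens=corpus.vocabulary.tokens,
    )


def estimate_uinvite(
    corpus: Corpus,
    init: EstimatorResult,
    seed: int,
    theta: float = 0.4,
    max_sweeps: int = 50,
) -> EstimatorResult:
    """Hill-climbing over single-edge toggles of an unweighted network.

    A toggle (add or remove one undirected edge) is accepted iff the corpus
    CRW log-likelihood under the jump-augmented evaluation model strictly
    increases; sweeps visit candidate edges in a seeded random order and the
    search stops when a full sweep accepts nothing.  (The original method's
    edge-ordering heuristics are replaced by this randomized sweep; the
    acceptance rule is identical.)
    """
    rng = np.random.default_rng(seed)
    W = corpus.vocabulary.size
    freq = corpus.vocabulary.list_frequency.astype(float)
    rho = freq / freq.sum()

    def loglik(adj: np.ndarray) -> float:
        p = row_normalize(adj, isolated="zero")
        model = attach_jump_tpm(p, theta, rho)
        return corpus_loglik(model, corpus, start="jump")[0]

    a = init.adjacency.binarized()
    current = loglik(a)
    if not np.isfinite(current):
        raise ValueError("initial network has zero corpus likelihood")
    candidates = list(itertools.combinations(range(W), 2))
    for _ in range(max_sweeps):
        accepted = False
        for idx in rng.permutation(len(candidates)):
            i, j = candidates[idx]
            a[i, j] = a[j, i] = 1.0 - a[i, j]
            trial = loglik(a)
            if trial > current:
                current = trial
                accepted = True
            else:
                a[i, j] = a[j, i] = 1.0 - a[i, j]
        if not accepted:
            break
    return EstimatorResult(
        AdjacencyMatrix(a, directed=False, weighted=False),
        provenance=_prov(corpus, "uinvite", seed=seed, theta=theta,
                         note="randomized-sweep hill climb"),
        tokens=corpus.vocabulary.tokens,
    )


# ---------------------------------------------------------------------------
# weighted (bigram) methods


def bigram_counts(corpus: Corpus) -> np.ndarray:
    """Directed counts of ordered adjacent word pairs over all lists."""
    W = corpus.vocabulary.size
    a = np.zeros((W, W))
    for fl in corpus.lists:
        for i, j in zip(fl.words, fl.words[1:]):
            a[i, j] += 1.0
    return a


def estimate_bigram_fixed(corpus: Corpus) -> EstimatorResult:
    return EstimatorResult(
        AdjacencyMatrix(bigram_counts(corpus), directed=True, weighted=True),
        provenance=_prov(corpus, "bigram-fixed"),
        tokens=corpus.vocabulary.tokens,
    )


def estimate_bigram_ind(
    corpus: Corpus, config: EstimatorConfig | None = None
) -> EstimatorResult:
    """Prune bigram edges below a count threshold; the removed outgoing weight
    of each node becomes its jump weight, so jump probabilities are
    node-specific.  Landing weights are the list frequencies."""
    config = config or EstimatorConfig()
    counts = bigram_counts(corpus)
    pruned = np.where(counts >= config.prune_threshold, counts, 0.0)
    theta_w = (counts - pruned).sum(axis=1)
    rho_w = corpus.vocabulary.list_frequency.astype(float)
    return EstimatorResult(
        AdjacencyMatrix(pruned, directed=True, weighted=True),
        jump=JumpWeights(theta_w, rho_w),
        provenance=_prov(corpus, "bigram-ind", prune_threshold=config.prune_threshold),
        tokens=corpus.vocabulary.tokens,
    )


def _gamma_power(counts: np.ndarray, gamma: float) -> np.ndarray:
    """Element-wise power with 0**gamma = 0 for every gamma (including 0)."""
    out = np.zeros_like(counts, dtype=float)
    pos = counts > 0
    out[pos] = counts[pos] ** gamma
    return out


def estimate_bigram_cn(
    corpus: Corpus,
    cn_mask: AdjacencyMatrix | EstimatorResult,
    config: EstimatorConfig | None = None,
) -> EstimatorResult:
    """BIGRAM-CN: bigram counts raised to gamma, masked by the CN network.

    Off-mask weight is pooled per source node into its jump weight (the sum
    of the weights of the edges deemed irrelevant); landing weights are the
    list frequencies.
    """
    config = config or EstimatorConfig()
    if isinstance(cn_mask, EstimatorResult):
        cn_mask = cn_mask.adjacency
    mask = cn_mask.binarized()
    if mask.shape[0] != corpus.vocabulary.size:
        raise ValueError("mask vocabulary size mismatch")
    powered = _gamma_power(bigram_counts(corpus), config.gamma)
    a_bcn = mask * powered
    theta_w = ((1.0 - mask) * powered).sum(axis=1)
    rho_w = corpus.vocabulary.list_frequency.astype(float)
    return EstimatorResult(
        AdjacencyMatrix(a_bcn, directed=True, weighted=True),
        jump=JumpWeights(theta_w, rho_w),
        provenance=_prov(corpus, "bigram-cn", gamma=config.gamma),
        tokens=corpus.vocabulary.tokens,
    )


# ---------------------------------------------------------------------------
# bridging to transition models


def to_transition_model(
    result: EstimatorResult,
    corpus: Corpus,
    theta: float | None = None,
) -> TransitionModel:
    """Turn an estimator result into a jump-augmented transition model.

    Results carrying their own jump weights (BIGRAM-IND/-CN) are bordered and
    row-normalized directly; nodes with no outgoing mass at all get
    ``theta_i = 1`` (all mass to the jump state).  Results without jump
    weights need a scalar ``theta``; the landing distribution is proportional
    to the list frequencies.
    """
    freq = corpus.vocabulary.list_frequency.astype(float)
    tokens = result.tokens or corpus.vocabulary.tokens
    if result.jump is not None:
        a = result.adjacency.weights
        th = result.jump.theta_weights.copy()
        out_mass = a.sum(axis=1) + th
        th = np.where(out_mass == 0, 1.0, th)  # isolated nodes jump surely
        rho_w = result.jump.landing_weights
        out_mass = a.sum(axis=1) + th
        local = a / out_mass[:, None]
        return TransitionModel(local, th / out_mass, rho_w / rho_w.sum(), tokens)
    if theta is None:
        raise ValueError("unweighted estimator result needs a scalar theta")
    p = row_normalize(result.adjacency, isolated="zero")
    return attach_jump_tpm(p, theta, freq / freq.sum(), tokens)


ESTIMATORS = {
    "fe": estimate_fe,
    "nrw": estimate_nrw,
    "pf": estimate_pathfinder,
    "cn": estimate_cn,
    "cbn": estimate_cbn,
    "bigram-fixed": estimate_bigram_fixed,
    "bigram-ind": estimate_bigram_ind,
}
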