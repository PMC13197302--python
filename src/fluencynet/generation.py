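"""Synthetic fluency-list generation and seeded ground-truth models.

Sampling a list is a literal censored random walk on the full transition
matrix: the walk starts at the jump state (or at a frequency-drawn word for
models without jumps), each step samples the current row, semantic nodes are
recorded on first visit only, and the jump state may be revisited but is
never recorded.  The walk ends once the requested number of distinct words
has been emitted.

Ground-truth models have block-clustered local weights (dense within
clusters, sparse between), a Zipfian landing distribution, and per-node jump
probabilities drawn from a range — a scaled-down analogue of the clustered
transition structure of real fluency corpora, used for parameter-recovery
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Corpus, FluencyList, LengthModel, Vocabulary
from .markov import StartPolicy, TransitionModel, attach_jump_tpm, row_normalize

__all__ = ["GroundTruthSpec", "sample_list", "sample_corpus", "make_ground_truth"]

_STEP_CAP = 1_000_000


@dataclass(frozen=True)
class GroundTruthSpec:
    """Parameters of a synthetic generating model.

    Defaults are the standing recovery-study conditions: 20 words in 4
    clusters, strong within-cluster weights, weak bridges, moderate
    node-specific jump probabilities and a Zipfian landing distribution.
    """

    n_words: int = 20
    n_clusters: int = 4
    within_cluster_weight: float = 8.0
    between_cluster_weight: float = 0.4
    between_density: float = 0.1  # fraction of between-cluster pairs bridged
    # jump probabilities average ~0.15: in real fluency corpora the large
    # majority of transitions (~7 in 8) stay within the local component
    theta_range: tuple[float, float] = (0.05, 0.25)
    frequency_skew: float = 1.0  # Zipf exponent of the landing weights
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_cluster_weight < 0 or self.between_cluster_weight < 0:
            raise ValueError("cluster weights must be nonnegative")
        if self.n_clusters < 1 or self.n_clusters > self.n_words:
            raise ValueError("need 1 <= n_clusters <= n_words")

    def cluster_of(self) -> np.ndarray:
        """Cluster label per word (contiguous blocks, balanced sizes)."""
        return np.arange(self.n_words) * self.n_clusters // self.n_words


def make_ground_truth(spec: GroundTruthSpec) -> TransitionModel:
    """Seeded block-structured jump-augmented model satisfying all
    transition-model invariants."""
    rng = np.random.default_rng(spec.seed)
    W = spec.n_words
    labels = spec.cluster_of()
    same = labels[:, None] == labels[None, :]
    base = np.where(same, spec.within_cluster_weight, spec.between_cluster_weight)
    rho_w = 1.0 / np.arange(1, W + 1, dtype=float) ** spec.frequency_skew
    rng.shuffle(rho_w)  # decouple frequency rank from cluster layout
    # association strengths in real fluency data are strongly skewed and
    # coupled to word frequency; log-normal dispersion plus a frequency
    # factor reproduces that heterogeneity
    noise = np.exp(rng.normal(0.0, 0.75, size=(W, W)))
    freq_factor = np.sqrt(np.outer(rho_w, rho_w))
    a = base * noise * freq_factor / freq_factor.mean()
    # local structure is dense within clusters but sparse between: only a
    # few bridges exist, global moves are mediated by the jump state
    bridge = rng.random((W, W)) < spec.between_density
    a = np.where(same | bridge, a, 0.0)
    a = (a + a.T) / 2.0  # undirected local structure
    np.fill_diagonal(a, 0.0)
    lo, hi = spec.theta_range
    theta = np.clip(rng.uniform(lo, hi, size=W), 0.0, 1.0)
    p = row_normalize(a, isolated="zero")
    model = attach_jump_tpm(
        p, theta, rho_w / rho_w.sum(), tokens=tuple(f"w{i:02d}" for i in range(W))
    )
    return _self_consistent_landing(model)


def _self_consistent_landing(model: TransitionModel, max_iter: int = 300) -> TransitionModel:
    """Iterate the landing distribution to the stationary distribution of the
    reabsorbed chain.

    In the model family assumed by the estimators, the landing distribution
    is proportional to word frequency; a ground truth whose landings match
    its own long-run visitation frequencies reproduces that property instead
    of contradicting it.  Fixed point of ``rho -> stationary(local + theta
    rho)``; convergence is geometric.
    """
    if model.theta.max() <= 0:
        return model
    rho = model.rho.copy()
    for _ in range(max_iter):
        p_abs = model.local + np.outer(model.theta, rho)
        vals, vecs = np.linalg.eig(p_abs.T)
        pi = np.abs(np.real(vecs[:, np.argmin(np.abs(vals - 1.0))]))
        pi /= pi.sum()
        if np.abs(pi - rho).max() < 1e-13:
            break
        rho = pi
    return TransitionModel(model.local, model.theta, rho, model.tokens)


def sample_list(
    model: TransitionModel,
    length: int,
    rng: np.random.Generator,
    start: StartPolicy = "jump",
    start_dist: np.ndarray | None = None,
    list_id: str = "synthetic",
) -> FluencyList:
    """Sample one censored walk of `length` distinct emitted words."""
    W = model.n_words
    if length > W:
        raise ValueError("length exceeds vocabulary size")
    full = model.full
    cum = np.cumsum(full, axis=1)
    emitted: list[int] = []
    seen = np.zeros(W + 1, dtype=bool)
    if start == "jump":
        state = 0
    elif start == "frequency":
        dist = start_dist if start_dist is not None else model.rho
        state = int(rng.choice(W, p=dist / dist.sum())) + 1
        emitted.append(state - 1)
        seen[state] = True
    else:
        raise ValueError(f"unknown start policy {start!r}")
    steps = 0
    while len(emitted) < length:
        steps += 1
        if steps > _STEP_CAP:
            import warnings

            warnings.warn("walk trapped; list truncated at step cap", stacklevel=2)
            break
        state = int(np.searchsorted(cum[state], rng.random(), side="right"))
        if state > 0 and not seen[state]:
            seen[state] = True
            emitted.append(state - 1)
    if not emitted:
        raise RuntimeError("walk emitted no words")
    return FluencyList(list_id, tuple(emitted))


def sample_corpus(
    model: TransitionModel,
    n_lists: int,
    length_model: LengthModel,
    seed: int,
    start: StartPolicy = "jump",
    start_dist: np.ndarray | None = None,
) -> Corpus:
    """Sample independent lists with lengths drawn from the length model
    (clipped to [1, W]); vocabulary frequencies are rebuilt from the sample.

    The corpus shares the model's token namespace so ids remain comparable.
    """
    rng = np.random.default_rng(seed)
    W = model.n_words
    lengths = np.clip(length_model.sample(n_lists, rng), 1, W)
    lists = [
        sample_list(model, int(lam), rng, start, start_dist, list_id=f"S{i:05d}")
        for i, lam in enumerate(lengths)
    ]
    freq = np.zeros(W, dtype=np.int64)
    for fl in lists:
        for w in fl.words:
            freq[w] += 1
    tokens = model.tokens or tuple(f"w{i:02d}" for i in range(W))
    return Corpus(tuple(lists), Vocabulary(tokens, freq))
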