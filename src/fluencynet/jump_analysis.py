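"""Validation of model-derived jump probabilities against category switches.

A transition between adjacent words is labeled a *switch* ("jump") when the
two words share no semantic category in an external annotation.  The model's
jump probabilities are then scored as predictors of those labels (ROC/AUC
with DeLong comparison), alongside two simpler topological predictors:
inverted node degree and inverted semantic cohesion (the probability of
returning to a node within three steps of the reabsorbed chain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .corpus import CategoryAnnotation, Corpus
from .markov import ReabsorbedModel, TransitionModel, adjusted_jump_probability

logger = logging.getLogger(__name__)

__all__ = [
    "SwitchLabels",
    "RocResult",
    "node_degree",
    "semantic_cohesion",
    "label_switches",
    "roc_auc",
    "delong_test",
    "rank_correlation",
    "jump_trajectory",
]


@dataclass(frozen=True)
class SwitchLabels:
    """Per-transition binary labels (1 = jump) with their list/position keys."""

    labels: np.ndarray  # int {0,1}
    keys: tuple[tuple[str, int], ...]  # (list_id, transition index within list)
    n_excluded: int


@dataclass(frozen=True)
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None


def node_degree(adjacency: np.ndarray) -> np.ndarray:
    """Undirected degree on the binarized local structure."""
    b = (np.asarray(adjacency) > 0)
    b = b | b.T
    np.fill_diagonal(b, False)
    return b.sum(axis=1).astype(int)


def semantic_cohesion(
    reabsorbed: ReabsorbedModel | np.ndarray, node: int, steps: int = 3
) -> float:
    """P(return to `node` within `steps` steps) on the reabsorbed chain.

    Computed by propagating the occupancy vector while masking the node's
    column after each hit: hit probabilities at steps 1..k are accumulated
    and survivors continue.  Step-1 self-returns count (the reabsorbed
    diagonal may be positive).
    """
    p = reabsorbed.p_abs if isinstance(reabsorbed, ReabsorbedModel) else np.asarray(reabsorbed)
    v = np.zeros(p.shape[0])
    v[node] = 1.0
    total = 0.0
    for _ in range(steps):
        v = v @ p
        total += v[node]
        v[node] = 0.0
    return float(total)


def label_switches(corpus: Corpus, annotation: CategoryAnnotation) -> SwitchLabels:
    """1 where adjacent words share no category; transitions touching an
    unannotated word are excluded (count logged)."""
    labels: list[int] = []
    keys: list[tuple[str, int]] = []
    excluded = 0
    for fl in corpus.lists:
        for k, (a, b) in enumerate(zip(fl.words, fl.words[1:])):
            shared = annotation.shared(a, b)
            if shared is None:
                excluded += 1
                continue
            labels.append(0 if shared else 1)
            keys.append((fl.list_id, k))
    if excluded:
        logger.info("excluded %d transitions with unannotated words", excluded)
    return SwitchLabels(np.asarray(labels, dtype=int), tuple(keys), excluded)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """AUC by the rank (Mann-Whitney) statistic with tie correction, plus the
    monotone ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative labels")
    ranks = stats.rankdata(scores)  # midranks handle ties
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(1 - sorted_labels)
    # collapse threshold ties so the curve is monotone in both coordinates
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return RocResult(float(auc), fpr, tpr, n_pos, n_neg, scores, labels)


def _delong_structural_components(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placement values via midranks (handles ties, O((m+n) log(m+n)))
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n  # per-positive components
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # per-negative components
    auc = v10.mean()
    return auc, v10, v01


def delong_test(a: RocResult, b: RocResult) -> tuple[float, float]:
    """DeLong's paired test comparing two correlated AUCs on shared labels.

    Returns (Z, two-sided p).  Antisymmetric under swapping the inputs.
    """
    if a.scores is None or b.scores is None:
        raise ValueError("RocResult must carry scores for the DeLong test")
    if not np.array_equal(a.labels, b.labels):
        raise ValueError("DeLong test requires identical label vectors")
    auc_a, v10_a, v01_a = _delong_structural_components(a.scores, a.labels)
    auc_b, v10_b, v01_b = _delong_structural_components(b.scores, b.labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def rank_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (rho, p)."""
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def jump_trajectory(
    model: TransitionModel, words: list[int]
) -> list[tuple[float, float]]:
    """(base, adjusted) jump probability after each prefix of a list —
    plot-ready data for cluster-depletion trajectories."""
    return [
        adjusted_jump_probability(model, words[: k + 1]) for k in range(len(words))
    ]
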