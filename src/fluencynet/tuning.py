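"""Fivefold cross-validated selection of scalar model hyperparameters.

Folds contain whole lists (no list straddles a split), the score is the
pooled gLL on the held-out fold after unseen-word mapping, and ties break
toward the smaller parameter value (sparser/simpler models).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .corpus import Corpus, map_unseen_words, split_corpus, _subcorpus
from .markov import TransitionModel, corpus_gll

__all__ = ["CvResult", "kfold_split", "tune_scalar"]


@dataclass(frozen=True)
class CvResult:
    param_name: str
    grid: tuple
    mean_gll: tuple[float, ...]
    per_fold: tuple[tuple[float, ...], ...]  # one tuple per grid value
    selected: float | int

    def as_dict(self) -> dict:
        return {
            "param_name": self.param_name,
            "grid": list(self.grid),
            "mean_gll": list(self.mean_gll),
            "per_fold": [list(row) for row in self.per_fold],
            "selected": self.selected,
        }


def kfold_split(
    corpus: Corpus, k: int = 5, seed: int = 0
) -> list[tuple[Corpus, Corpus]]:
    """Whole-list partition into k folds; deterministic given the seed.

    Returns (train, validation) pairs; validation folds are pairwise
    disjoint and their union is the corpus.
    """
    n = corpus.n_lists
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= number of lists")
    rng = np.random.default_rng(seed)
    # key the shuffle to list ids so fold composition does not depend on the
    # order lists happen to be stored in
    by_id = np.argsort([fl.list_id for fl in corpus.lists], kind="stable")
    order = by_id[rng.permutation(n)]
    folds = np.array_split(order, k)
    pairs = []
    for fold in folds:
        fold_set = set(fold.tolist())
        val = [fl for i, fl in enumerate(corpus.lists) if i in fold_set]
        train = [fl for i, fl in enumerate(corpus.lists) if i not in fold_set]
        pairs.append((_subcorpus(corpus, train), _subcorpus(corpus, val)))
    return pairs


def tune_scalar(
    corpus: Corpus,
    model_factory: Callable[[Corpus, float | int], TransitionModel],
    param_name: str,
    grid: Sequence[float | int],
    k: int = 5,
    seed: int = 0,
) -> CvResult:
    """Grid search by k-fold CV on validation gLL.

    ``model_factory(train_corpus, value)`` must return a fitted
    :class:`TransitionModel`.  For each grid value the factory is fitted on
    each fold's training part and scored (pooled gLL, start policy "jump")
    on its validation part after unseen-word mapping.  The selected value
    maximizes the mean validation gLL; ties break toward the smaller value.
    """
    if len(grid) == 0:
        raise ValueError("empty grid")
    folds = kfold_split(corpus, k, seed)
    mapped = []
    for fi, (tr, va) in enumerate(folds):
        va_mapped, _ = map_unseen_words(va, tr, seed=seed + 1000 + fi)
        mapped.append((tr, va_mapped))
    per_fold: list[tuple[float, ...]] = []
    means: list[float] = []
    for value in grid:
        scores = []
        for tr, va in mapped:
            model = model_factory(tr, value)
            gll, _ = corpus_gll(model, va, start="jump")
            scores.append(gll)
        per_fold.append(tuple(scores))
        means.append(float(np.mean(scores)))
    means_arr = np.asarray(means)
    if np.all(means_arr == 0.0):
        raise ValueError(
            "all grid values give zero validation likelihood; "
            "attach a jump state so every transition is possible"
        )
    best = means_arr.max()
    # tie-break toward the smaller parameter value
    candidates = [g for g, m in zip(grid, means_arr) if m >= best - 1e-15]
    selected = min(candidates)
    return CvResult(param_name, tuple(grid), tuple(means), tuple(per_fold), selected)
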