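"""Fluency-list corpora: I/O, vocabularies, splits, and the list-length model.

A *fluency list* is the ordered, repeat-free sequence of category exemplars a
participant produces (e.g., clothing items in two minutes).  A *corpus* is a
collection of such lists over a shared vocabulary; it is the observational
unit every estimator and metric in this package consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "Vocabulary",
    "FluencyList",
    "Corpus",
    "LengthModel",
    "CategoryAnnotation",
    "read_corpus",
    "write_corpus",
    "corpus_from_token_lists",
    "split_corpus",
    "map_unseen_words",
    "fit_length_model",
]


class CorpusFormatError(ValueError):
    """Raised when an input file does not match the expected corpus layout."""


@dataclass(frozen=True)
class Vocabulary:
    """Token <-> contiguous integer id bijection with per-token list frequencies.

    ``list_frequency[w]`` counts the number of lists containing token ``w``
    (each list contributes at most once per token): the quantity written
    ``f_w`` in the landing distribution and the frequency-likelihood metric.
    """

    tokens: tuple[str, ...]
    list_frequency: np.ndarray  # int array, aligned with tokens

    def __post_init__(self) -> None:
        if len(self.tokens) != len(set(self.tokens)):
            raise ValueError("duplicate tokens in vocabulary")
        freq = np.asarray(self.list_frequency, dtype=np.int64)
        object.__setattr__(self, "list_frequency", freq)
        if len(freq) != len(self.tokens):
            raise ValueError("list_frequency length mismatch")

    @property
    def size(self) -> int:
        return len(self.tokens)

    def id_of(self, token: str) -> int:
        return self._index[token]

    @property
    def _index(self) -> dict[str, int]:
        idx = self.__dict__.get("_index_cache")
        if idx is None:
            idx = {t: i for i, t in enumerate(self.tokens)}
            self.__dict__["_index_cache"] = idx
        return idx

    def __contains__(self, token: str) -> bool:
        return token in self._index


@dataclass(frozen=True)
class FluencyList:
    """One participant's ordered, repeat-free word sequence (token ids)."""

    list_id: str
    words: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.words) < 1:
            raise ValueError(f"list {self.list_id!r} is empty")
        if len(set(self.words)) != len(self.words):
            raise ValueError(f"list {self.list_id!r} contains a repeated token id")

    @property
    def length(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class Corpus:
    lists: tuple[FluencyList, ...]
    vocabulary: Vocabulary

    def __post_init__(self) -> None:
        W = self.vocabulary.size
        for fl in self.lists:
            for w in fl.words:
                if not (0 <= w < W):
                    raise ValueError(f"token id {w} outside vocabulary in {fl.list_id!r}")

    @property
    def n_lists(self) -> int:
        return len(self.lists)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([fl.length for fl in self.lists], dtype=np.int64)

    @property
    def mean_length(self) -> float:
        return float(self.lengths.mean()) if self.lists else float("nan")

    def tokens_of(self, fl: FluencyList) -> list[str]:
        return [self.vocabulary.tokens[w] for w in fl.words]


@dataclass(frozen=True)
class LengthModel:
    """Discretized normal model of list lengths.

    Integer length ``k`` receives the normal mass of ``[k - 1/2, k + 1/2)``,
    renormalized over the truncated support ``1..l_max``.
    """

    mu: float
    sigma: float
    l_max: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.l_max < 1:
            raise ValueError("l_max must be >= 1")

    @property
    def support(self) -> np.ndarray:
        return np.arange(1, self.l_max + 1)

    def pmf(self) -> np.ndarray:
        k = self.support
        raw = stats.norm.cdf(k + 0.5, self.mu, self.sigma) - stats.norm.cdf(
            k - 0.5, self.mu, self.sigma
        )
        total = raw.sum()
        if total <= 0:
            raise ValueError("length model has no mass on its support")
        return raw / total

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pmf())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.support, size=n, p=self.pmf())


@dataclass(frozen=True)
class CategoryAnnotation:
    """Token id -> set of semantic category labels (words may carry several)."""

    categories: dict[int, frozenset[str]] = field(default_factory=dict)

    def shared(self, a: int, b: int) -> bool | None:
        """True if a and b share a category; None if either is unannotated."""
        ca, cb = self.categories.get(a), self.categories.get(b)
        if ca is None or cb is None:
            return None
        return bool(ca & cb)


# ---------------------------------------------------------------------------
# construction and I/O


def corpus_from_token_lists(
    token_lists: dict[str, list[str]] | list[list[str]],
) -> Corpus:
    """Build a :class:`Corpus` from raw token sequences.

    Within-list duplicates are censored to the first occurrence (the number of
    drops is logged); the vocabulary is rebuilt in order of first appearance.
    """
    if not isinstance(token_lists, dict):
        token_lists = {f"L{i:04d}": toks for i, toks in enumerate(token_lists)}
    vocab_order: dict[str, int] = {}
    cleaned: list[tuple[str, list[str]]] = []
    n_drops = 0
    for list_id, toks in token_lists.items():
        seen: set[str] = set()
        kept: list[str] = []
        for t in toks:
            t = str(t).strip()
            if not t:
                continue
            if t in seen:
                n_drops += 1
                continue
            seen.add(t)
            kept.append(t)
            if t not in vocab_order:
                vocab_order[t] = len(vocab_order)
        if kept:
            cleaned.append((list_id, kept))
    if n_drops:
        logger.info("censored %d within-list duplicate tokens to first occurrence", n_drops)
    if not cleaned:
        raise CorpusFormatError("empty corpus: no nonempty lists")
    tokens = tuple(vocab_order)
    freq = np.zeros(len(tokens), dtype=np.int64)
    lists = []
    for list_id, kept in cleaned:
        ids = tuple(vocab_order[t] for t in kept)
        for w in ids:
            freq[w] += 1
        lists.append(FluencyList(list_id, ids))
    return Corpus(tuple(lists), Vocabulary(tokens, freq))


def read_corpus(path, dialect: str = "long") -> Corpus:
    """Read a corpus from disk.

    ``dialect="long"``: UTF-8 CSV with header ``list_id,position,token``
    (positions 1-based within each list).  ``dialect="lines"``: one list per
    line, tokens separated by semicolons.
    """
    if dialect == "lines":
        with open(path, encoding="utf-8") as fh:
            rows = [ln.strip() for ln in fh if ln.strip()]
        if not rows:
            raise CorpusFormatError(f"{path}: empty file")
        return corpus_from_token_lists([r.split(";") for r in rows])
    if dialect != "long":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, dtype={"list_id": str, "token": str})
    required = {"list_id", "position", "token"}
    if not required.issubset(df.columns):
        raise CorpusFormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    if df.empty:
        raise CorpusFormatError(f"{path}: empty corpus")
    token_lists: dict[str, list[str]] = {}
    for list_id, grp in df.groupby("list_id", sort=False):
        pos = grp["position"].to_numpy()
        if not np.array_equal(np.sort(pos), np.arange(1, len(pos) + 1)):
            warnings.warn(
                f"list {list_id!r}: non-contiguous positions; ordering by given values",
                stacklevel=2,
            )
        token_lists[str(list_id)] = list(grp.sort_values("position")["token"])
    return corpus_from_token_lists(token_lists)


def write_corpus(corpus: Corpus, path) -> None:
    """Write a corpus as long-format CSV (`list_id,position,token`)."""
    rows = [
        (fl.list_id, pos + 1, corpus.vocabulary.tokens[w])
        for fl in corpus.lists
        for pos, w in enumerate(fl.words)
    ]
    pd.DataFrame(rows, columns=["list_id", "position", "token"]).to_csv(path, index=False)


def write_vocabulary(corpus: Corpus, path) -> None:
    """Export the vocabulary as TSV ``token<TAB>id<TAB>list_frequency``."""
    voc = corpus.vocabulary
    pd.DataFrame(
        {"token": voc.tokens, "id": np.arange(voc.size), "list_frequency": voc.list_frequency}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# splitting and unseen-word mapping


def _subcorpus(corpus: Corpus, keep: list[FluencyList]) -> Corpus:
    """Re-materialize a corpus over the same token namespace (ids preserved)."""
    freq = np.zeros(corpus.vocabulary.size, dtype=np.int64)
    for fl in keep:
        for w in fl.words:
            freq[w] += 1
    voc = Vocabulary(corpus.vocabulary.tokens, freq)
    return Corpus(tuple(keep), voc)


def split_corpus(
    corpus: Corpus, test_fraction: float, seed: int
) -> tuple[Corpus, Corpus]:
    """Hold out whole lists: ``round(test_fraction * N)`` go to the test split.

    Rounding is half-up, and the draw is deterministic given ``seed``.  Both
    returned corpora keep the parent token namespace so ids stay comparable.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = corpus.n_lists
    n_test = int(np.floor(test_fraction * n + 0.5))
    if n_test == 0 or n_test == n:
        raise ValueError(f"test_fraction {test_fraction} yields an empty partition")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_idx = set(order[:n_test].tolist())
    test = [fl for i, fl in enumerate(corpus.lists) if i in test_idx]
    train = [fl for i, fl in enumerate(corpus.lists) if i not in test_idx]
    return _subcorpus(corpus, train), _subcorpus(corpus, test)


def map_unseen_words(
    test: Corpus, train: Corpus, seed: int
) -> tuple[Corpus, dict[int, int]]:
    """Swap test tokens absent from the training vocabulary.

    Each unseen token is replaced by a uniformly sampled training token of
    equal list frequency (nearest frequency if no exact match; ties broken
    toward the lower frequency, then lexicographically).  If the sampled
    replacement already occurs in the receiving list it is resampled; if all
    candidates are exhausted the word is dropped and logged.  Returns the
    remapped corpus and the replacement table (old id -> new id).
    """
    if train.vocabulary.size == 0 or train.vocabulary.list_frequency.sum() == 0:
        raise ValueError("training vocabulary is empty")
    rng = np.random.default_rng(seed)
    train_freq = train.vocabulary.list_frequency
    present = np.flatnonzero(train_freq > 0)
    unseen = [
        w
        for w in range(test.vocabulary.size)
        if test.vocabulary.list_frequency[w] > 0
        and (w >= train.vocabulary.size or train_freq[w] == 0)
    ]
    table: dict[int, int] = {}
    for w in unseen:
        f = int(test.vocabulary.list_frequency[w])
        diffs = np.abs(train_freq[present] - f)
        best = diffs.min()
        cands = present[diffs == best]
        # prefer lower frequency on a distance tie, then lexicographic token order
        freqs = train_freq[cands]
        cands = cands[freqs == freqs.min()]
        cands = np.array(sorted(cands, key=lambda i: train.vocabulary.tokens[i]))
        table[w] = int(cands[0]) if len(cands) == 1 else int(rng.choice(cands))
    new_lists: list[FluencyList] = []
    n_dropped = 0
    for fl in test.lists:
        words: list[int] = []
        for w in fl.words:
            if w not in table:
                words.append(w)
                continue
            repl = table[w]
            if repl in words or repl in fl.words:
                # resample among equal-preference candidates not already in the list
                f = int(test.vocabulary.list_frequency[w])
                diffs = np.abs(train_freq[present] - f)
                cands = [
                    int(c)
                    for c in present[diffs == diffs.min()]
                    if c not in words and c not in fl.words
                ]
                if not cands:
                    n_dropped += 1
                    continue
                repl = int(rng.choice(np.array(cands)))
            words.append(repl)
        if words:
            new_lists.append(FluencyList(fl.list_id, tuple(words)))
    if n_dropped:
        logger.info("dropped %d unseen tokens with no admissible replacement", n_dropped)
    return _subcorpus(test, new_lists), table


# ---------------------------------------------------------------------------
# list-length model

_SIGMA_FLOOR = 0.5


def fit_length_model(corpus: Corpus, l_max: int | None = None) -> LengthModel:
    """Maximum-likelihood discretized-normal fit to the list lengths.

    The mass of integer ``k`` is proportional to
    ``Phi((k+1/2-mu)/sigma) - Phi((k-1/2-mu)/sigma)`` truncated to
    ``1..l_max`` (default ``min`` of the largest observed length times 2 and
    the vocabulary size).  Degenerate samples (all lengths equal) get
    ``sigma`` floored at 0.5 with a warning.
    """
    lengths = corpus.lengths
    if len(lengths) < 2:
        raise ValueError("need at least 2 lists to fit a length model")
    if l_max is None:
        l_max = int(min(2 * lengths.max(), max(corpus.vocabulary.size, lengths.max())))
    if lengths.max() > l_max:
        raise ValueError("observed length exceeds l_max")
    if np.ptp(lengths) == 0:
        warnings.warn("all lengths equal; sigma floored at 0.5", stacklevel=2)
        return LengthModel(float(lengths[0]), _SIGMA_FLOOR, l_max)

    k = np.arange(1, l_max + 1)
    counts = np.bincount(lengths, minlength=l_max + 1)[1:]

    def nll(params: np.ndarray) -> float:
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        raw = stats.norm.cdf(k + 0.5, mu, sigma) - stats.norm.cdf(k - 0.5, mu, sigma)
        total = raw.sum()
        if total <= 0 or not np.isfinite(total):
            return 1e300
        with np.errstate(divide="ignore"):
            logp = np.log(raw) - np.log(total)
        ll = float((counts * logp).sum())
        return -ll if np.isfinite(ll) else 1e300

    x0 = np.array([lengths.mean(), np.log(max(lengths.std(ddof=0), _SIGMA_FLOOR))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10})
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    if sigma < _SIGMA_FLOOR:
        warnings.warn("fitted sigma below floor; clamped to 0.5", stacklevel=2)
        sigma = _SIGMA_FLOOR
    return LengthModel(mu, sigma, l_max)
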