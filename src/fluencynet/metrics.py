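"""Quality metrics for fluency models: gLL, fLL, nRB and their statistics.

Three complementary views of how well a model (or a population) matches a
reference corpus:

* **gLL** — geometric-mean per-emission probability of the lists under a
  transition model (computed in :mod:`fluencynet.markov`); distributions of
  per-list values are summarized with beta fits.
* **fLL** — frequency likelihood: geometric mean of length-adjusted word
  occurrence probabilities relative to the reference corpus, asking "are the
  produced words as frequent as expected?".
* **nRB** — normalized count of adjacent word pairs that are statistically
  relevant (the conceptual-network edge set), with the list-length trend
  regressed out, asking "do words associate as expected?".

The statistical apparatus (beta/Gaussian fits, shortest credible intervals,
parametric-bootstrap KS tests, BIC-approximation Bayes factors, density
overlap, bootstrap CIs, BIC, bigram R^2) lives here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .corpus import Corpus, FluencyList, LengthModel
from .estimators import EstimatorConfig, bigram_counts, estimate_cn
from .markov import TransitionModel, corpus_gll

__all__ = [
    "BetaFit",
    "GaussianFit",
    "fll_list",
    "fll_corpus",
    "relevant_pairs",
    "relevant_bigram_count",
    "nrb_slope",
    "nrb_list",
    "nrb_corpus",
    "fit_beta",
    "fit_gaussian",
    "ks_test",
    "ks_test_two_sample",
    "ks_discretized_normal",
    "bayes_factor01_fit",
    "bayes_factor01_two_sample",
    "overlap_coefficient",
    "bootstrap_ci",
    "bic_score",
    "bigram_r2",
]

_EPS = 1e-9


# ---------------------------------------------------------------------------
# frequency likelihood (fLL)


def fll_list(
    words: FluencyList | list[int],
    reference: Corpus,
    mean_length: float | None = None,
) -> float:
    """Frequency likelihood of one list against a reference corpus.

    ``fLL = (prod_i [1 - (1 - f_wi/N)^(lambda/lambda_bar)])^(1/lambda)``
    where ``f_wi`` is the number of reference lists containing word ``w_i``,
    ``N`` the number of reference lists, ``lambda`` the list length and
    ``lambda_bar`` the reference mean length.  A word absent from the
    reference zeroes the product (map unseen words first).
    """
    ids = list(words.words if isinstance(words, FluencyList) else words)
    N = reference.n_lists
    lam_bar = mean_length if mean_length is not None else reference.mean_length
    lam = len(ids)
    f = reference.vocabulary.list_frequency[ids].astype(float)
    if (f == 0).any():
        warnings.warn("list contains words absent from the reference; fLL = 0",
                      stacklevel=2)
        return 0.0
    factors = 1.0 - (1.0 - f / N) ** (lam / lam_bar)
    return float(np.exp(np.log(factors).sum() / lam))


def fll_corpus(corpus: Corpus, reference: Corpus) -> tuple[float, np.ndarray]:
    """Geometric mean of the per-list fLL values, plus the per-list vector."""
    vals = np.array([fll_list(fl, reference) for fl in corpus.lists])
    if (vals == 0).any():
        return 0.0, vals
    return float(np.exp(np.log(vals).mean())), vals


# ---------------------------------------------------------------------------
# normalized relevant bigrams (nRB)


def relevant_pairs(
    reference: Corpus, config: EstimatorConfig | None = None
) -> frozenset[tuple[int, int]]:
    """The set R of statistically relevant unordered word pairs: the edge set
    of the conceptual network estimated on the reference corpus."""
    if reference.n_lists == 0:
        return frozenset()
    result = estimate_cn(reference, config or EstimatorConfig())
    i, j = np.nonzero(np.triu(result.adjacency.weights))
    return frozenset(zip(i.tolist(), j.tolist()))


def relevant_bigram_count(
    words: FluencyList | list[int], pairs: frozenset[tuple[int, int]]
) -> int:
    """C: number of adjacent pairs of the list that belong to R."""
    ids = list(words.words if isinstance(words, FluencyList) else words)
    c = 0
    for a, b in zip(ids, ids[1:]):
        if (min(a, b), max(a, b)) in pairs:
            c += 1
    return c


def nrb_slope(
    reference: Corpus, pairs: frozenset[tuple[int, int]]
) -> float:
    """Least-squares slope of C against list length on the reference corpus."""
    lengths = reference.lengths.astype(float)
    counts = np.array([relevant_bigram_count(fl, pairs) for fl in reference.lists],
                      dtype=float)
    if np.ptp(lengths) == 0:
        return 0.0
    return float(np.polyfit(lengths, counts, 1)[0])


def nrb_list(
    words: FluencyList | list[int],
    pairs: frozenset[tuple[int, int]],
    slope: float,
    mean_length: float,
) -> float:
    """C* = C - m (lambda - lambda_bar): the length-detrended relevant-bigram
    count, scored on the reference scale."""
    ids = list(words.words if isinstance(words, FluencyList) else words)
    c = relevant_bigram_count(ids, pairs)
    return float(c - slope * (len(ids) - mean_length))


def nrb_corpus(
    corpus: Corpus,
    pairs: frozenset[tuple[int, int]],
    slope: float,
    mean_length: float,
) -> np.ndarray:
    return np.array([nrb_list(fl, pairs, slope, mean_length) for fl in corpus.lists])


# ---------------------------------------------------------------------------
# distribution fits


@dataclass(frozen=True)
class BetaFit:
    alpha: float
    beta: float
    sci_mass: float = 0.5
    sci: tuple[float, float] = field(default=(np.nan, np.nan))

    @property
    def mode(self) -> float:
        a, b = self.alpha, self.beta
        if a > 1 and b > 1:
            return (a - 1) / (a + b - 2)
        return float("nan")

    def frozen(self):
        return stats.beta(self.alpha, self.beta)


@dataclass(frozen=True)
class GaussianFit:
    mean: float
    sd: float

    def frozen(self):
        return stats.norm(self.mean, self.sd)


def shortest_credible_interval(dist, mass: float = 0.5) -> tuple[float, float]:
    """Shortest interval containing `mass` of a (unimodal) fitted density."""
    if mass >= 1.0:
        return float(dist.ppf(0.0)), float(dist.ppf(1.0))

    def width(lo_q: float) -> float:
        return dist.ppf(lo_q + mass) - dist.ppf(lo_q)

    res = optimize.minimize_scalar(width, bounds=(1e-12, 1 - mass - 1e-12),
                                   method="bounded")
    lo_q = float(res.x)
    return float(dist.ppf(lo_q)), float(dist.ppf(lo_q + mass))


def fit_beta(values: np.ndarray, sci_mass: float = 0.5) -> BetaFit:
    """Maximum-likelihood beta shape fit on (0,1); values are clipped away
    from the endpoints first.  The SCI is found by density-threshold search
    over the fitted distribution."""
    v = np.clip(np.asarray(values, dtype=float), _EPS, 1 - _EPS)
    a, b, _, _ = stats.beta.fit(v, floc=0.0, fscale=1.0)
    fit = BetaFit(float(a), float(b), sci_mass)
    sci = shortest_credible_interval(fit.frozen(), sci_mass)
    return BetaFit(float(a), float(b), sci_mass, sci)


def fit_gaussian(values: np.ndarray) -> GaussianFit:
    v = np.asarray(values, dtype=float)
    return GaussianFit(float(v.mean()), float(v.std(ddof=1) if len(v) > 1 else 0.0))


# ---------------------------------------------------------------------------
# goodness-of-fit tests


def _refit(kind: str, sample: np.ndarray):
    if kind == "beta":
        v = np.clip(sample, _EPS, 1 - _EPS)
        a, b, _, _ = stats.beta.fit(v, floc=0.0, fscale=1.0)
        return stats.beta(a, b)
    if kind == "norm":
        return stats.norm(sample.mean(), max(sample.std(ddof=0), 1e-12))
    raise ValueError(kind)


def ks_test(
    values: np.ndarray,
    kind: str = "beta",
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sample KS test against a fitted distribution with the p-value
    calibrated by parametric bootstrap (fit-refit on simulated samples),
    since the shape parameters were estimated from the same data."""
    v = np.asarray(values, dtype=float)
    fitted = _refit(kind, v)
    stat = float(stats.kstest(v, fitted.cdf).statistic)
    rng = np.random.default_rng(seed)
    n = len(v)
    exceed = 0
    for _ in range(n_boot):
        sim = fitted.rvs(size=n, random_state=rng)
        refit = _refit(kind, sim)
        if stats.kstest(sim, refit.cdf).statistic >= stat:
            exceed += 1
    return stat, (exceed + 1) / (n_boot + 1)


def ks_test_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    res = stats.ks_2samp(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def ks_discretized_normal(
    lengths: np.ndarray, model: LengthModel, n_boot: int = 200, seed: int = 0
) -> tuple[float, float]:
    """KS test of integer list lengths against a discretized-normal model,
    comparing CDFs on the integer support with a parametric-bootstrap
    p-value."""
    lengths = np.asarray(lengths, dtype=np.int64)
    support = model.support
    model_cdf = model.cdf()

    def ks_stat(sample: np.ndarray) -> float:
        emp = np.searchsorted(np.sort(sample), support, side="right") / len(sample)
        return float(np.abs(emp - model_cdf).max())

    stat = ks_stat(lengths)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        sim = model.sample(len(lengths), rng)
        if ks_stat(sim) >= stat:
            exceed += 1
    return stat, (exceed + 1) / (n_boot + 1)


# ---------------------------------------------------------------------------
# Bayes factors (BIC approximation; method recorded in reports)


def _hist_loglik_and_params(v: np.ndarray) -> tuple[float, int]:
    """Log-likelihood of a histogram density with Sturges bins (the
    nonparametric alternative of the goodness-of-fit Bayes factor)."""
    n = len(v)
    n_bins = max(int(np.ceil(np.log2(n) + 1)), 2)
    counts, edges = np.histogram(v, bins=n_bins)
    widths = np.diff(edges)
    with np.errstate(divide="ignore"):
        log_dens = np.where(counts > 0, np.log(counts / (n * widths)), -np.inf)
    ll = float((counts * np.where(counts > 0, log_dens, 0.0)).sum())
    return ll, n_bins - 1


def bayes_factor01_fit(values: np.ndarray, kind: str = "beta") -> float:
    """BF01 for "the data follow the fitted parametric family" via the BIC
    approximation: null = fitted family, alternative = histogram density.
    Values > 1 favor the fit."""
    v = np.asarray(values, dtype=float)
    if len(v) < 10:
        warnings.warn("fewer than 10 values; BF01 is highly uncertain", stacklevel=2)
    fitted = _refit(kind, v)
    ll0 = float(fitted.logpdf(np.clip(v, _EPS, 1 - _EPS) if kind == "beta" else v).sum())
    k0 = 2
    ll1, k1 = _hist_loglik_and_params(v)
    n = len(v)
    bic0 = k0 * np.log(n) - 2 * ll0
    bic1 = k1 * np.log(n) - 2 * ll1
    return float(np.exp(np.clip((bic1 - bic0) / 2.0, -700, 700)))


def bayes_factor01_two_sample(
    a: np.ndarray, b: np.ndarray, kind: str = "norm"
) -> float:
    """BF01 for "both samples share one distribution" via the BIC
    approximation: null = one fit of the family to the pooled data,
    alternative = separate fits.  Values > 1 favor the null."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(len(a), len(b)) < 10:
        warnings.warn("fewer than 10 values; BF01 is highly uncertain", stacklevel=2)
    pooled = np.concatenate([a, b])

    def ll(sample: np.ndarray, fitted) -> float:
        x = np.clip(sample, _EPS, 1 - _EPS) if kind == "beta" else sample
        return float(fitted.logpdf(x).sum())

    f0 = _refit(kind, pooled)
    fa, fb = _refit(kind, a), _refit(kind, b)
    n = len(pooled)
    bic0 = 2 * np.log(n) - 2 * ll(pooled, f0)
    bic1 = 4 * np.log(n) - 2 * (ll(a, fa) + ll(b, fb))
    return float(np.exp(np.clip((bic1 - bic0) / 2.0, -700, 700)))


# ---------------------------------------------------------------------------
# overlap, bootstrap, BIC, R^2


def overlap_coefficient(dist_a, dist_b, grid_size: int = 200_001) -> float:
    """100 * integral of min(pdf_a, pdf_b): percentage similarity of two
    fitted densities, by dense trapezoid quadrature over the joint support."""
    lo = min(dist_a.ppf(1e-9), dist_b.ppf(1e-9))
    hi = max(dist_a.ppf(1 - 1e-9), dist_b.ppf(1 - 1e-9))
    if not np.isfinite(lo) or not np.isfinite(hi) or hi <= lo:
        return 0.0
    x = np.linspace(lo, hi, grid_size)
    m = np.minimum(dist_a.pdf(x), dist_b.pdf(x))
    m = np.where(np.isfinite(m), m, 0.0)
    return float(100.0 * np.trapezoid(m, x))


def bootstrap_ci(
    values: np.ndarray,
    statistic: str = "mean",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI of the arithmetic ("mean") or geometric
    ("gmean") mean."""
    v = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(v), size=(n_boot, len(v)))
    samples = v[idx]
    if statistic == "gmean":
        with np.errstate(divide="ignore"):
            reps = np.exp(np.log(np.maximum(samples, _EPS)).mean(axis=1))
    elif statistic == "mean":
        reps = samples.mean(axis=1)
    else:
        raise ValueError(statistic)
    lo, hi = np.quantile(reps, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def bic_score(total_loglik: float, n_params: int, n_obs: int) -> float:
    """BIC = k ln(n) - 2 ln L with n = total emissions (sum of list lengths)."""
    return float(n_params * np.log(n_obs) - 2.0 * total_loglik)


def model_n_params(method: str, result_or_model, mask_nnz: int | None = None,
                   n_words: int | None = None) -> int:
    """Parameter counts used for BIC, per estimation method."""
    if method in {"fe", "nrw", "pf", "cn", "cbn"}:
        a = result_or_model.adjacency.weights
        return int((np.triu(a) > 0).sum()) + 1  # edges + scalar jump prob
    if method == "uinvite":
        W = result_or_model.adjacency.weights.shape[0]
        return W * (W - 1) // 2
    if method in {"bigram-fixed"}:
        a = result_or_model.adjacency.weights
        return int((a > 0).sum()) + 1
    if method in {"bigram-ind", "bigram-cn"}:
        a = result_or_model.adjacency.weights
        return int((a > 0).sum()) + a.shape[0]  # nonzero local weights + theta
    if method == "invite":
        return n_words * (n_words - 1)
    if method == "invite-cn":
        return mask_nnz + 2 * n_words - 1
    raise ValueError(f"unknown method {method!r}")


def bigram_r2(
    counts_candidate: np.ndarray | dict,
    counts_reference: np.ndarray | dict,
    pairs: frozenset[tuple[int, int]] | None = None,
) -> float:
    """R^2 between bigram count vectors, reference as target; restricted to
    the relevant pair set when one is given.  May be negative."""
    if isinstance(counts_candidate, dict) or isinstance(counts_reference, dict):
        keys = sorted(set(counts_candidate) | set(counts_reference))
        y = np.array([counts_reference.get(k, 0) for k in keys], dtype=float)
        x = np.array([counts_candidate.get(k, 0) for k in keys], dtype=float)
    else:
        cc = np.asarray(counts_candidate, dtype=float)
        cr = np.asarray(counts_reference, dtype=float)
        if pairs is not None:
            sel = np.array(sorted(pairs))
            if len(sel) == 0:
                return float("nan")
            # undirected: pool both directions
            x = cc[sel[:, 0], sel[:, 1]] + cc[sel[:, 1], sel[:, 0]]
            y = cr[sel[:, 0], sel[:, 1]] + cr[sel[:, 1], sel[:, 0]]
        else:
            nz = (cc > 0) | (cr > 0)
            x, y = cc[nz], cr[nz]
    ss_res = float(((y - x) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else float("-inf")
    return 1.0 - ss_res / ss_tot


def corpus_bigram_counts(corpus: Corpus) -> np.ndarray:
    """Directed adjacent-pair counts of a corpus (alias into estimators)."""
    return bigram_counts(corpus)


# ---------------------------------------------------------------------------
# convenience: the pooled gLL re-export used by reports

corpus_gll = corpus_gll
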