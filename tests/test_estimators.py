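"""Network estimators: rule checks, oracles, and conservation properties."""

import itertools

import numpy as np
import pytest

from fluencynet import corpus_from_token_lists
from fluencynet.estimators import (
    CN_2_3,
    EstimatorConfig,
    bigram_counts,
    cn_exceedance_probability,
    estimate_bigram_cn,
    estimate_bigram_fixed,
    estimate_bigram_ind,
    estimate_cbn,
    estimate_cn,
    estimate_fe,
    estimate_nrw,
    estimate_pathfinder,
    estimate_uinvite,
    positional_distance_matrix,
    _minimax_distances,
    to_transition_model,
)
from fluencynet.generation import GroundTruthSpec, make_ground_truth, sample_corpus
from fluencynet.corpus import LengthModel
from fluencynet.markov import corpus_loglik


class TestUnweightedRules:
    def test_fe_first_bigram_only(self):
        c = corpus_from_token_lists([["a", "b", "c"], ["b", "a"]])
        a = estimate_fe(c).adjacency.weights
        ia, ib, ic = (c.vocabulary.id_of(t) for t in "abc")
        assert a[ia, ib] == a[ib, ia] == 1.0
        assert a.sum() == 2.0  # the single undirected edge

    def test_fe_idempotent_over_repeats(self):
        c = corpus_from_token_lists([["x", "y", f"z{i}"] for i in range(6)])
        a = estimate_fe(c).adjacency.weights
        assert a.sum() == 2.0

    def test_nrw_all_adjacent_pairs(self):
        c = corpus_from_token_lists([["a", "b", "c"]])
        a = estimate_nrw(c).adjacency.weights
        assert a.sum() == 4.0  # edges a-b and b-c, symmetric

    def test_fe_subset_of_nrw(self, tiny_corpus):
        fe = estimate_fe(tiny_corpus).adjacency.weights
        nrw = estimate_nrw(tiny_corpus).adjacency.weights
        assert ((fe > 0) <= (nrw > 0)).all()


class TestPathfinder:
    def test_triangle_prune(self):
        # direct distance a-c (2) exceeds the minimax path a-b-c (max 1)
        d = np.array([[np.inf, 1.0, 2.0], [1.0, np.inf, 1.0], [2.0, 1.0, np.inf]])
        m = _minimax_distances(d)
        keep = np.isfinite(d) & (d <= m + 1e-12)
        assert not keep[0, 2] and keep[0, 1] and keep[1, 2]

    def test_single_list_pair(self):
        c = corpus_from_token_lists([["a", "b"]])
        a = estimate_pathfinder(c).adjacency.weights
        assert a.sum() == 2.0

    def test_minimax_against_brute_force(self):
        """Retained edges match exhaustive path enumeration on 8 nodes."""
        rng = np.random.default_rng(14)
        n = 8
        d = rng.uniform(1, 10, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, np.inf)
        m = _minimax_distances(d)
        # brute force: minimax over all simple paths
        for i, j in itertools.combinations(range(n), 2):
            best = d[i, j]
            for r in range(1, n - 1):
                for mids in itertools.permutations(
                    [k for k in range(n) if k not in (i, j)], r
                ):
                    path = [i, *mids, j]
                    best = min(best, max(d[u, v] for u, v in zip(path, path[1:])))
            assert m[i, j] == pytest.approx(best)

    def test_positional_distance(self):
        c = corpus_from_token_lists([["a", "b", "c"], ["a", "c"]])
        d = positional_distance_matrix(c)
        ia, ic = c.vocabulary.id_of("a"), c.vocabulary.id_of("c")
        assert d[ia, ic] == pytest.approx(1.5)  # (2 + 1) / 2


class TestConceptualNetwork:
    def test_maximal_evidence_pair(self):
        lists = [["a", "b", f"f{i}", f"g{i}", f"h{i}", f"k{i}"] for i in range(100)]
        c = corpus_from_token_lists(lists)
        a = estimate_cn(c, EstimatorConfig(window=2, min_cooc=3)).adjacency.weights
        ia, ib = c.vocabulary.id_of("a"), c.vocabulary.id_of("b")
        assert a[ia, ib] == 1.0

    def test_never_within_window(self):
        lists = [["a", f"x{i}", f"y{i}", f"z{i}", "b"] for i in range(30)]
        c = corpus_from_token_lists(lists)
        a = estimate_cn(c, EstimatorConfig(window=2, min_cooc=1)).adjacency.weights
        ia, ib = c.vocabulary.id_of("a"), c.vocabulary.id_of("b")
        assert a[ia, ib] == 0.0

    def test_exceedance_matches_enumeration(self):
        """Exact within-window null probabilities vs exhaustive placement
        enumeration for short lists."""
        rng = np.random.default_rng(6)
        for window in (1, 2, 3):
            lengths = rng.integers(2, 7, size=5)
            # enumeration: for each list, P(pair within window) by counting
            per_list = []
            for lam in lengths:
                pairs = list(itertools.combinations(range(lam), 2))
                close = sum(1 for i, j in pairs if j - i <= window)
                per_list.append(close / len(pairs))
            # brute-force exceedance via full outcome enumeration
            for observed in range(len(lengths) + 1):
                exact = 0.0
                for outcome in itertools.product([0, 1], repeat=len(lengths)):
                    if sum(outcome) >= observed:
                        pr = 1.0
                        for o, p in zip(outcome, per_list):
                            pr *= p if o else (1 - p)
                        exact += pr
                got = cn_exceedance_probability(np.array(lengths), window, observed)
                assert got == pytest.approx(exact, abs=1e-12)

    def test_min_cooc_monotone(self):
        rng = np.random.default_rng(30)
        toks = [f"w{i}" for i in range(12)]
        lists = {f"L{j}": list(rng.choice(toks, size=6, replace=False))
                 for j in range(60)}
        c = corpus_from_token_lists(lists)
        prev = None
        for mc in (1, 2, 3, 4):
            a = estimate_cn(c, EstimatorConfig(window=2, min_cooc=mc)).adjacency.weights
            if prev is not None:
                assert ((a > 0) <= (prev > 0)).all()
            prev = a


class TestCorrelationNetwork:
    def test_k4_retained(self):
        rng = np.random.default_rng(9)
        toks = ["a", "b", "c", "d"]
        lists = {f"L{j}": [t for t in toks if rng.random() < 0.6] or ["a"]
                 for j in range(30)}
        c = corpus_from_token_lists(lists)
        a = estimate_cbn(c).adjacency.weights
        W = c.vocabulary.size
        assert (a > 0).sum() / 2 <= 3 * (W - 2) if W >= 3 else True
        # K4 is planar: every pair with finite correlation can be kept
        assert (a > 0).sum() / 2 == W * (W - 1) / 2

    def test_planar_edge_bound_w5(self):
        rng = np.random.default_rng(10)
        toks = list("abcde")
        lists = {}
        for j in range(200):
            k = rng.integers(2, 6)
            lists[f"L{j}"] = list(rng.choice(toks, size=k, replace=False))
        c = corpus_from_token_lists(lists)
        a = estimate_cbn(c).adjacency.weights
        assert (a > 0).sum() / 2 <= 3 * (5 - 2)

    def test_identical_columns_rank_first(self):
        lists = {}
        for j in range(20):
            row = ["p", "q"] if j % 2 == 0 else ["r", "s"]
            lists[f"L{j}"] = row
        c = corpus_from_token_lists(lists)
        a = estimate_cbn(c).adjacency.weights
        ip, iq = c.vocabulary.id_of("p"), c.vocabulary.id_of("q")
        assert a[ip, iq] == 1.0


class TestBigramFamily:
    def test_directed_counts(self):
        lists = {f"A{i}": ["a", "b"] for i in range(7)}
        lists.update({f"B{i}": ["b", "a"] for i in range(2)})
        c = corpus_from_token_lists(lists)
        a = estimate_bigram_fixed(c).adjacency.weights
        ia, ib = c.vocabulary.id_of("a"), c.vocabulary.id_of("b")
        assert a[ia, ib] == 7 and a[ib, ia] == 2

    def test_count_conservation(self, tiny_corpus):
        a = bigram_counts(tiny_corpus)
        assert a.sum() == sum(fl.length - 1 for fl in tiny_corpus.lists)

    def test_ind_pooling_arithmetic(self):
        lists = {}
        # node a: outgoing counts 5 (to b), 3 (to c), 1 (to d)
        for i in range(5):
            lists[f"x{i}"] = ["a", "b"]
        for i in range(3):
            lists[f"y{i}"] = ["a", "c"]
        lists["z0"] = ["a", "d"]
        c = corpus_from_token_lists(lists)
        r = estimate_bigram_ind(c, EstimatorConfig(prune_threshold=4))
        ia = c.vocabulary.id_of("a")
        assert r.adjacency.weights[ia].sum() == 5.0
        assert r.jump.theta_weights[ia] == 4.0

    def test_ind_threshold_one_is_identity(self, tiny_corpus):
        r = estimate_bigram_ind(tiny_corpus, EstimatorConfig(prune_threshold=1))
        np.testing.assert_array_equal(
            r.adjacency.weights, estimate_bigram_fixed(tiny_corpus).adjacency.weights
        )
        assert (r.jump.theta_weights == 0).all()

    def test_mass_conservation(self, tiny_corpus):
        counts = bigram_counts(tiny_corpus)
        for thr in (1, 2, 3):
            r = estimate_bigram_ind(tiny_corpus, EstimatorConfig(prune_threshold=thr))
            np.testing.assert_allclose(
                r.adjacency.weights.sum(axis=1) + r.jump.theta_weights,
                counts.sum(axis=1),
            )

    def test_bigram_cn_gamma_zero_binary(self, tiny_corpus):
        mask = estimate_nrw(tiny_corpus)  # any binary mask with support
        r = estimate_bigram_cn(tiny_corpus, mask, EstimatorConfig(gamma=0.0))
        w = r.adjacency.weights
        assert set(np.unique(w)) <= {0.0, 1.0}

    def test_bigram_cn_gamma_half(self):
        lists = {}
        for i in range(4):
            lists[f"x{i}"] = ["a", "b"]
        for i in range(9):
            lists[f"y{i}"] = ["b", "c"]
        c = corpus_from_token_lists(lists)
        mask = estimate_nrw(c)
        r = estimate_bigram_cn(c, mask, EstimatorConfig(gamma=0.5))
        ia, ib, ic = (c.vocabulary.id_of(t) for t in "abc")
        assert r.adjacency.weights[ia, ib] == pytest.approx(2.0)
        assert r.adjacency.weights[ib, ic] == pytest.approx(3.0)

    def test_bigram_cn_full_mask_identity(self, tiny_corpus):
        W = tiny_corpus.vocabulary.size
        from fluencynet.markov import AdjacencyMatrix

        ones = AdjacencyMatrix(1.0 - np.eye(W), directed=True)
        r = estimate_bigram_cn(tiny_corpus, ones, EstimatorConfig(gamma=1.0))
        assert (r.jump.theta_weights == 0).all()
        np.testing.assert_array_equal(r.adjacency.weights, bigram_counts(tiny_corpus))

    def test_bigram_cn_mass_conservation_at_gamma_one(self, tiny_corpus):
        mask = estimate_cn(tiny_corpus, EstimatorConfig(window=2, min_cooc=1, alpha=0.5))
        r = estimate_bigram_cn(tiny_corpus, mask, EstimatorConfig(gamma=1.0))
        counts = bigram_counts(tiny_corpus)
        np.testing.assert_allclose(
            r.adjacency.weights.sum(axis=1) + r.jump.theta_weights,
            counts.sum(axis=1),
        )


class TestUInvite:
    def _corpus(self):
        rng = np.random.default_rng(12)
        truth = make_ground_truth(GroundTruthSpec(n_words=5, n_clusters=1, seed=3))
        return sample_corpus(truth, 30, LengthModel(3.5, 1.0, 5), seed=4)

    def test_likelihood_never_decreases(self):
        c = self._corpus()
        init = estimate_nrw(c)
        freq = c.vocabulary.list_frequency.astype(float)
        from fluencynet.markov import attach_jump_tpm, row_normalize

        def ll(result):
            p = row_normalize(result.adjacency.binarized(), isolated="zero")
            m = attach_jump_tpm(p, 0.4, freq / freq.sum())
            return corpus_loglik(m, c)[0]

        refined = estimate_uinvite(c, init, seed=0, theta=0.4, max_sweeps=3)
        assert ll(refined) >= ll(init)

    def test_reproducible_given_seed(self):
        c = self._corpus()
        init = estimate_nrw(c)
        r1 = estimate_uinvite(c, init, seed=5, theta=0.4, max_sweeps=2)
        r2 = estimate_uinvite(c, init, seed=5, theta=0.4, max_sweeps=2)
        np.testing.assert_array_equal(r1.adjacency.weights, r2.adjacency.weights)


class TestFuzzedConservation:
    """Row-stochasticity of every estimator's jump-augmented model."""

    @pytest.mark.parametrize("seed", range(5))
    def test_full_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        toks = [f"w{i}" for i in range(10)]
        lists = {}
        for j in range(25):
            k = rng.integers(2, 7)
            lists[f"L{j}"] = list(rng.choice(toks, size=k, replace=False))
        c = corpus_from_token_lists(lists)
        builders = {
            "fe": lambda: estimate_fe(c),
            "nrw": lambda: estimate_nrw(c),
            "pf": lambda: estimate_pathfinder(c),
            "cn": lambda: estimate_cn(c, EstimatorConfig(window=2, min_cooc=1, alpha=0.5)),
            "cbn": lambda: estimate_cbn(c),
            "bigram-fixed": lambda: estimate_bigram_fixed(c),
            "bigram-ind": lambda: estimate_bigram_ind(c, EstimatorConfig(prune_threshold=2)),
            "bigram-cn": lambda: estimate_bigram_cn(
                c, estimate_nrw(c), EstimatorConfig(gamma=1.0)),
        }
        for name, build in builders.items():
            result = build()
            theta = None if result.jump is not None else 0.3
            m = to_transition_model(result, c, theta=theta)
            np.testing.assert_allclose(
                m.full.sum(axis=1), 1.0, atol=1e-12, err_msg=name
            )
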