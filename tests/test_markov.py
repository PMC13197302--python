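"""Transition-model construction and censored-walk likelihood machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import mc_next_word_freq, random_jump_model
from fluencynet.markov import (
    AdjacencyMatrix,
    JumpWeights,
    adjusted_jump_probability,
    attach_jump_adjacency,
    attach_jump_tpm,
    corpus_gll,
    crw_transition_dist,
    crw_transition_prob,
    list_loglik,
    reabsorb,
    row_normalize,
)
from fluencynet import corpus_from_token_lists


class TestRowNormalize:
    @pytest.mark.parametrize(
        "a,expected",
        [
            ([[0, 1], [1, 0]], [[0, 1], [1, 0]]),
            (
                [[0, 2, 2], [1, 0, 0], [0, 3, 1]],
                [[0, 0.5, 0.5], [1, 0, 0], [0, 0.75, 0.25]],
            ),
        ],
    )
    def test_direct_arithmetic(self, a, expected):
        np.testing.assert_allclose(row_normalize(np.array(a, float)), expected)

    def test_degree_asymmetry(self):
        """2 vs 3 neighbors: p_ij = 1/2 while p_ji = 1/3."""
        a = np.zeros((5, 5))
        # node 0 connects to {1, 2}; node 1 connects to {0, 3, 4}
        for i, j in [(0, 1), (0, 2), (1, 3), (1, 4)]:
            a[i, j] = a[j, i] = 1.0
        p = row_normalize(a)
        assert p[0, 1] == 0.5
        assert p[1, 0] == pytest.approx(1 / 3)

    def test_zero_row_raises(self):
        a = np.zeros((2, 2))
        a[0, 1] = 1.0
        with pytest.raises(ValueError, match="no outgoing weight"):
            row_normalize(a)


class TestAttachJump:
    def test_row_scaling(self):
        p = np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])
        m = attach_jump_tpm(p, 0.2, np.full(3, 1 / 3))
        np.testing.assert_allclose(m.full[1], [0.2, 0.0, 0.4, 0.4])

    def test_theta_zero_identity(self):
        p = np.array([[0.0, 1.0], [1.0, 0.0]])
        m = attach_jump_tpm(p, 0.0, np.array([0.3, 0.7]))
        np.testing.assert_allclose(m.local, p)

    def test_theta_one_degenerate(self):
        p = np.array([[0.0, 1.0], [1.0, 0.0]])
        m = attach_jump_tpm(p, 1.0, np.array([0.5, 0.5]))
        np.testing.assert_allclose(m.full[1:], [[1, 0, 0], [1, 0, 0]])

    def test_adjacency_border_theta(self):
        """Outgoing weight 6 with jump weight 2 gives theta = 0.25."""
        a = np.array([[0.0, 3.0, 3.0], [1.0, 0.0, 1.0], [2.0, 2.0, 0.0]])
        m = attach_jump_adjacency(
            AdjacencyMatrix(a, directed=True), JumpWeights(np.array([2.0, 0.0, 0.0]),
                                                           np.ones(3))
        )
        assert m.theta[0] == pytest.approx(0.25)

    def test_border_consistent_with_tpm_route(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0.1, 1, (4, 4))
        np.fill_diagonal(a, 0)
        rho_w = rng.uniform(0.5, 2, 4)
        via_border = attach_jump_adjacency(
            AdjacencyMatrix(a, directed=True), JumpWeights(np.zeros(4), rho_w))
        via_tpm = attach_jump_tpm(row_normalize(a), 0.0, rho_w / rho_w.sum())
        np.testing.assert_allclose(via_border.full, via_tpm.full, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rows_stochastic_property(self, seed):
        rng = np.random.default_rng(seed)
        m = random_jump_model(rng)
        np.testing.assert_allclose(m.full.sum(axis=1), 1.0, atol=1e-12)


class TestReabsorb:
    def test_pure_jump(self):
        m = attach_jump_tpm(np.array([[0.0, 1.0], [1.0, 0.0]]), 1.0,
                            np.array([0.3, 0.7]))
        np.testing.assert_allclose(reabsorb(m).p_abs, [[0.3, 0.7], [0.3, 0.7]])

    def test_theta_zero_identity(self):
        p = np.array([[0.0, 1.0], [1.0, 0.0]])
        m = attach_jump_tpm(p, 0.0, np.array([0.5, 0.5]))
        np.testing.assert_allclose(reabsorb(m).p_abs, p)

    def test_equivalence_with_explicit_jump(self):
        """Absorption distributions agree between the full matrix (jump
        transient) and the reabsorbed matrix, for every prefix."""
        from itertools import permutations

        rng = np.random.default_rng(21)
        for _ in range(3):
            m = random_jump_model(rng)
            pa = reabsorb(m).p_abs
            for r in (1, 2, 3):
                for prefix in permutations(range(4), r):
                    d_full = crw_transition_dist(m, list(prefix))
                    d_abs = _absorption_on(pa, list(prefix))
                    np.testing.assert_allclose(d_full, d_abs, atol=1e-10)


def _absorption_on(p: np.ndarray, visited: list[int]) -> np.ndarray:
    """Absorption distribution on a plain W x W chain with `visited` transient."""
    n = p.shape[0]
    t = np.asarray(visited)
    mask = np.zeros(n, bool)
    mask[t] = True
    a_idx = np.flatnonzero(~mask)
    Q = p[np.ix_(t, t)]
    R = p[np.ix_(t, a_idx)]
    e = np.zeros(len(t))
    e[-1] = 1.0
    y = np.linalg.solve(np.eye(len(t)) - Q.T, e)
    out = np.zeros(n)
    out[a_idx] = y @ R
    return out


class TestCrwTransitions:
    def test_star_symmetry(self, star_model):
        assert crw_transition_prob(star_model, [0, 1], 2) == pytest.approx(0.5)

    def test_path_forced(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1.0
        m = attach_jump_tpm(row_normalize(a), 0.0, np.full(3, 1 / 3))
        assert crw_transition_prob(m, [1, 0], 2) == pytest.approx(1.0)

    def test_distribution_sums_to_one(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            m = random_jump_model(rng)
            prefix = list(rng.choice(6, size=rng.integers(1, 4), replace=False))
            assert crw_transition_dist(m, prefix).sum() == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(99)
        m = random_jump_model(rng)
        prefix = [2, 0]
        d = crw_transition_dist(m, prefix)
        n = 50_000
        freq = mc_next_word_freq(m, prefix, n, rng)
        se = np.sqrt(d * (1 - d) / n)
        ok = np.abs(freq - d) <= 3 * np.maximum(se, 1e-12)
        assert ok.all(), f"max z = {np.max(np.abs(freq - d) / np.maximum(se, 1e-12))}"

    def test_visited_target_rejected(self, star_model):
        with pytest.raises(ValueError, match="already visited"):
            crw_transition_prob(star_model, [0, 1], 1)


class TestListLikelihood:
    def test_star_composition(self, star_model):
        ll = list_loglik(star_model, [0, 1, 2], start="jump")
        assert ll == pytest.approx(np.log(1 / 4) + np.log(1 / 3) + np.log(1 / 2))

    def test_single_word(self, star_model):
        assert list_loglik(star_model, [2], start="jump") == pytest.approx(np.log(0.25))

    def test_impossible_transition(self):
        # two disconnected edges, no jump: a-b and c-d; list (a, c) impossible
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1.0
        m = attach_jump_tpm(row_normalize(a), 0.0, np.full(4, 0.25))
        assert list_loglik(m, [0, 2], start="jump") == -np.inf


class TestCorpusGll:
    def test_definition(self, star_model):
        c = corpus_from_token_lists([["H", "X", "Y"]])
        # token order of construction: H=0, X=1, Y=2 matches the star layout
        gll, per = corpus_gll(star_model, c, start="jump")
        expected = (0.25 * (1 / 3) * 0.5) ** (1 / 3)
        assert gll == pytest.approx(expected)
        assert per[0] == pytest.approx(expected)

    def test_reordering_invariance(self, tiny_corpus):
        rng = np.random.default_rng(2)
        m = random_jump_model(rng, n=5)
        gll1, _ = corpus_gll(m, tiny_corpus)
        from fluencynet.corpus import _subcorpus

        reordered = _subcorpus(tiny_corpus, list(tiny_corpus.lists[::-1]))
        gll2, _ = corpus_gll(m, reordered)
        assert gll1 == pytest.approx(gll2)

    def test_zero_likelihood_flags(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1.0
        m = attach_jump_tpm(row_normalize(a), 0.0, np.full(4, 0.25))
        c = corpus_from_token_lists({"ok": ["a", "b"], "bad": ["a", "c"]})
        with pytest.warns(UserWarning, match="zero likelihood"):
            gll, per = corpus_gll(m, c)
        assert gll == 0.0
        assert per[1] == 0.0 and per[0] > 0


class TestAdjustedJump:
    def test_single_node_equals_base(self):
        rng = np.random.default_rng(4)
        m = random_jump_model(rng)
        base, adj = adjusted_jump_probability(m, [3])
        assert adj == pytest.approx(base)

    def test_forced_jump(self):
        m = attach_jump_tpm(np.array([[0.0, 1.0], [1.0, 0.0]]), 1.0,
                            np.array([0.5, 0.5]))
        base, adj = adjusted_jump_probability(m, [0])
        assert base == adj == 1.0

    def test_adjusted_at_least_base(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            m = random_jump_model(rng)
            prefix = list(rng.choice(6, size=3, replace=False))
            base, adj = adjusted_jump_probability(m, prefix)
            assert adj >= base - 1e-12
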