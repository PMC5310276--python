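import math

import numpy as np
import pytest

from otutopics import (ConfigError, Corpus, Hyperparams, ValidationError,
                       fit_lda_gibbs, fold_in, joint_log_likelihood, perplexity)
from otutopics.lda_core import (GibbsState, collapsed_joint_ll,
                                exact_posterior_marginals, full_conditional)
from _helpers import enum_foldin_theta


def tiny_corpus():
    return Corpus([np.array([0, 1, 2]), np.array([0, 0, 2])],
                  ["a", "b", "c"], ["d1", "d2"])


def state_from(z_docs, corpus, K):
    tokens, doc_of = corpus.flatten()
    z = np.concatenate([np.asarray(zd, dtype=np.int64) for zd in z_docs])
    n_dk = np.zeros((corpus.n_docs, K), dtype=np.int64)
    n_kw = np.zeros((K, corpus.n_vocab), dtype=np.int64)
    np.add.at(n_dk, (doc_of, z), 1)
    np.add.at(n_kw, (z, tokens), 1)
    return GibbsState(tokens, doc_of, corpus.doc_lengths(), z, n_dk, n_kw,
                      n_kw.sum(axis=1), rng_seed=0)


class TestFullConditional:
    def test_hand_evaluated_example(self):
        # doc 0 = [w, w, x] and doc 1 = [y, x], all five tokens on topic 0.
        # Excluding token (0,0) leaves n_dk = [2,0], n_kw[., w] = [1,0],
        # n_k = [4,0]; with alpha = beta = 1 and V = 3 the unnormalised
        # conditional is [(2+1)(1+1)/(4+3), (0+1)(0+1)/(0+3)] = [6/7, 1/3],
        # normalised [0.72, 0.28].
        corpus = Corpus([np.array([0, 0, 1]), np.array([2, 1])],
                        ["w", "x", "y"], ["d1", "d2"])
        state = state_from([[0, 0, 0], [0, 0]], corpus, K=2)
        p = full_conditional(state, Hyperparams(2, 1.0, 1.0), d=0, i=0, w=0, V=3)
        assert np.allclose(p, [0.72, 0.28], atol=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_topic_returns_one(self):
        corpus = tiny_corpus()
        state = state_from([[0, 0, 0], [0, 0, 0]], corpus, K=1)
        p = full_conditional(state, Hyperparams(1, 1.0, 1.0), 0, 1, 1, 3)
        assert np.array_equal(p, [1.0])

    def test_symmetric_empty_counts_give_uniform(self):
        corpus = Corpus([np.array([1])], ["a", "b", "c"], ["d1"])
        state = state_from([[2]], corpus, K=4)
        p = full_conditional(state, Hyperparams(4, 0.7, 0.3), 0, 0, 1, 3)
        assert np.allclose(p, 0.25, atol=1e-12)


class TestJointLogLikelihood:
    def test_empty_state_is_zero(self):
        ll = collapsed_joint_ll(np.zeros((0, 2), dtype=int),
                                np.zeros((2, 3), dtype=int), 1.0, 1.0)
        assert ll == 0.0

    def test_hand_evaluated_value(self):
        # 1 doc, 2 copies of word 0, K=1, V=2, alpha=beta=1:
        # P(w, z) = Gamma(3)Gamma(1)/Gamma(4) = 1/3
        corpus = Corpus([np.array([0, 0])], ["a", "b"], ["d1"])
        state = state_from([[0, 0]], corpus, K=1)
        ll = joint_log_likelihood(state, Hyperparams(1, 1.0, 1.0), V=2)
        assert ll == pytest.approx(math.log(1 / 3), abs=1e-12)

    def test_invariant_under_topic_relabeling(self, rng):
        corpus = Corpus([rng.integers(0, 5, size=8) for _ in range(3)],
                        list("abcde"), ["d1", "d2", "d3"])
        z_docs = [rng.integers(0, 3, size=8) for _ in range(3)]
        hyper = Hyperparams(3, 0.5, 0.2)
        base = joint_log_likelihood(state_from(z_docs, corpus, 3), hyper, 5)
        for perm in [[1, 2, 0], [2, 1, 0], [0, 2, 1]]:
            relabeled = [np.array(perm)[z] for z in z_docs]
            ll = joint_log_likelihood(state_from(relabeled, corpus, 3), hyper, 5)
            assert ll == pytest.approx(base, abs=1e-9)

    def test_exchangeable_over_token_order(self, rng):
        corpus = Corpus([np.array([0, 1, 1, 2])], list("abc"), ["d1"])
        z = [np.array([0, 1, 0, 1])]
        hyper = Hyperparams(2, 1.0, 0.5)
        base = joint_log_likelihood(state_from(z, corpus, 2), hyper, 3)
        perm = rng.permutation(4)
        shuffled = Corpus([corpus.docs[0][perm]], list("abc"), ["d1"])
        ll = joint_log_likelihood(state_from([z[0][perm]], shuffled, 2), hyper, 3)
        assert ll == pytest.approx(base, abs=1e-12)


class TestFit:
    def test_single_topic_fit_is_exact(self):
        corpus = tiny_corpus()
        beta = 0.5
        fit = fit_lda_gibbs(corpus, Hyperparams(1, 1.0, beta), n_iter=20,
                            burn_in=5, sample_lag=3, seed=11)
        assert np.allclose(fit.theta, 1.0, atol=1e-12)
        n_w = np.bincount(np.concatenate(corpus.docs), minlength=3)
        expected = (n_w + beta) / (corpus.n_tokens + 3 * beta)
        assert np.allclose(fit.phi[0], expected, atol=1e-12)

    def test_same_seed_bit_identical(self):
        corpus = tiny_corpus()
        hyper = Hyperparams(3, 1.0, 0.1)
        a = fit_lda_gibbs(corpus, hyper, 50, 20, 2, seed=5)
        b = fit_lda_gibbs(corpus, hyper, 50, 20, 2, seed=5)
        assert np.array_equal(a.state.z, b.state.z)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.phi, b.phi)
        assert np.array_equal(a.trace, b.trace)

    def test_state_counts_consistent_and_rows_stochastic(self):
        corpus = tiny_corpus()
        fit = fit_lda_gibbs(corpus, Hyperparams(2, 0.5, 0.5), 30, 10, 1, seed=3)
        fit.state.check_consistency()
        assert np.allclose(fit.theta.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(fit.phi.sum(axis=1), 1.0, atol=1e-9)
        assert (fit.theta > 0).all() and (fit.phi > 0).all()

    def test_config_errors(self):
        corpus = tiny_corpus()
        with pytest.raises(ConfigError):
            fit_lda_gibbs(corpus, Hyperparams(2, 1.0, 1.0), n_iter=5, burn_in=5)
        with pytest.raises(ValidationError, match="no tokens"):
            fit_lda_gibbs(Corpus([np.array([0]), np.array([], dtype=int)],
                                 ["a", "b"], ["d1", "d2"]),
                          Hyperparams(2, 1.0, 1.0), 5, 1)

    def test_gibbs_marginals_match_enumeration_on_tiny_corpus(self):
        from otutopics import _gibbs
        corpus = Corpus([np.array([0, 1]), np.array([0, 2])], list("abc"),
                        ["d1", "d2"])
        hyper = Hyperparams(2, 1.0, 1.0)
        exact = exact_posterior_marginals(corpus, hyper)
        tokens, doc_of = corpus.flatten()
        z = np.empty(4, np.int64)
        n_dk = np.zeros((2, 2), np.int64)
        n_kw = np.zeros((2, 3), np.int64)
        n_k = np.zeros(2, np.int64)
        _gibbs.seed_rng(17)
        _gibbs.init_assignments(tokens, doc_of, 2, z, n_dk, n_kw, n_k)
        tally = np.zeros((4, 2), np.int64)
        n_sweeps = 50_000
        _gibbs.sweep_tally(tokens, doc_of, z, n_dk, n_kw, n_k, 1.0, 1.0,
                           n_sweeps, tally)
        assert np.abs(tally / n_sweeps - exact).max() < 0.03


class TestPerplexity:
    def test_uniform_phi_scores_vocab_size(self):
        corpus = tiny_corpus()
        phi = np.full((2, 3), 1 / 3)
        theta = np.array([[0.2, 0.8], [0.6, 0.4]])
        assert perplexity(phi, theta, corpus) == pytest.approx(3.0, abs=1e-12)

    def test_perfect_model_scores_one(self):
        corpus = Corpus([np.array([0, 0])], ["a", "b"], ["d1"])
        phi = np.array([[1.0, 0.0]])
        assert perplexity(phi, np.array([[1.0]]), corpus) == pytest.approx(1.0)

    def test_hand_evaluated_value(self):
        corpus = Corpus([np.array([0, 1])], ["a", "b"], ["d1"])
        phi = np.array([[0.75, 0.25]])
        expected = math.exp(-(math.log(0.75) + math.log(0.25)) / 2)
        assert perplexity(phi, np.array([[1.0]]), corpus) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(2.3094, abs=1e-4)

    def test_token_outside_vocabulary_rejected(self):
        corpus = Corpus([np.array([0, 1])], ["a", "b"], ["d1"])
        with pytest.raises(ValidationError):
            perplexity(np.array([[1.0]]), np.array([[1.0]]), corpus)


class TestFoldIn:
    def test_single_topic_gives_ones(self):
        corpus = tiny_corpus()
        theta = fold_in(np.full((1, 3), 1 / 3), corpus, Hyperparams(1, 1.0, 1.0),
                        n_iter=10, seed=0)
        assert np.allclose(theta, 1.0, atol=1e-12)

    def test_support_forces_topic_mass(self):
        phi = np.array([[0.5, 0.5, 0.0, 0.0], [0.0, 0.0, 0.5, 0.5]])
        corpus = Corpus([np.array([2, 3, 2])], list("abcd"), ["d1"])
        hyper = Hyperparams(2, 1.0, 0.1)
        theta = fold_in(phi, corpus, hyper, n_iter=50, seed=1)
        assert theta[0, 1] >= 3 / (3 + 2 * hyper.alpha) - 1e-12

    def test_matches_enumeration_expectation(self):
        rng = np.random.default_rng(42)
        phi = rng.dirichlet(np.ones(4), size=2)
        doc = np.array([0, 2, 3, 1])
        corpus = Corpus([doc], list("abcd"), ["d1"])
        hyper = Hyperparams(2, 0.8, 0.1)
        exact = enum_foldin_theta(phi, doc, hyper.alpha)
        est = fold_in(phi, corpus, hyper, n_iter=40_000, seed=9)
        assert np.abs(est[0] - exact).max() < 0.02

    def test_deterministic_under_seed(self):
        corpus = tiny_corpus()
        phi = np.full((2, 3), 1 / 3)
        hyper = Hyperparams(2, 1.0, 0.1)
        a = fold_in(phi, corpus, hyper, 100, seed=4)
        b = fold_in(phi, corpus, hyper, 100, seed=4)
        assert np.array_equal(a, b)
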