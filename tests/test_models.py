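import numpy as np
import pytest
from scipy.stats import binom

from fgsig import (ScoreSpec, build_factor_graph, cgf_moments, enumerate_tail,
                   is_normalized, jc69_expected_substitutions, jc69_rate_matrix,
                   jc69_transition, markov_model, max_score_pvalue, phylo_model,
                   poisson_binomial_model, pwm_model, saddlepoint_tail)
from fgsig.oracles import enumerate_distribution, simulate_ctmc


def seq_brute_force(A, r, L, init, transitions):
    """All A^L sequences with their path probabilities under an order-r chain."""
    seqs = np.array(list(np.ndindex(*(A,) * L)), dtype=np.int64)
    pow_ = A ** np.arange(r - 1, -1, -1)
    z = seqs[:, :r] @ pow_
    p = init[z]
    for i in range(L - r):
        nxt = seqs[:, r + i]
        p = p * transitions[i][z, nxt]
        z = (z % (A ** (r - 1))) * A + nxt if r > 1 else nxt
    return seqs, p


class TestPoissonBinomial:
    def test_fair_coins_tail(self):
        graph, score = poisson_binomial_model(np.full(10, 0.5))
        # C(10,8)+C(10,9)+C(10,10) = 56 of 1024
        assert np.isclose(enumerate_tail(graph, score, 7.5), 56 / 1024, rtol=1e-12)

    def test_equal_p_equals_binomial(self):
        graph, score = poisson_binomial_model(np.full(12, 0.3))
        dist = enumerate_distribution(graph, score)
        assert np.allclose(dist.support, np.arange(13))
        assert np.allclose(dist.probs, binom.pmf(np.arange(13), 12, 0.3), atol=1e-12)

    def test_weighted_support(self):
        graph, score = poisson_binomial_model([0.5, 0.5], s=[1.0, 2.0])
        dist = enumerate_distribution(graph, score)
        assert np.allclose(dist.support, [0, 1, 2, 3])
        assert np.allclose(dist.probs, 0.25)

    def test_validation(self):
        with pytest.raises(ValueError, match="empty"):
            poisson_binomial_model([])
        with pytest.raises(ValueError, match="0, 1"):
            poisson_binomial_model([1.5])

    def test_null_is_normalized(self):
        graph, _ = poisson_binomial_model(np.random.default_rng(0).random(50))
        assert is_normalized(graph, 1e-10)


class TestPwmModel:
    def test_uniform_motif_scores_zero(self):
        model = pwm_model(np.full((4, 1), 0.25))
        assert np.allclose(model.score.tables[0], 0.0)

    def test_dinucleotide_tail_matches_brute_force(self):
        rng = np.random.default_rng(5)
        pfm = rng.dirichlet(np.full(4, 0.8), size=2).T  # frequencies, 4x2
        model = pwm_model(pfm)
        W = np.log(pfm / 0.25)
        scores = (W[:, 0][:, None] + W[:, 1][None, :]).ravel()
        for t in np.quantile(scores, [0.25, 0.7, 0.95]):
            exact = np.sum(np.full(16, 1 / 16.0)[scores > t])
            assert np.isclose(enumerate_tail(model.graph, model.score, t), exact,
                              rtol=1e-10)

    def test_counts_with_pseudocount(self):
        counts = np.array([[8, 0], [0, 8], [1, 1], [1, 1]], dtype=float)
        model = pwm_model(counts, pseudocount=0.5)
        expected = (counts[:, 0] + 0.5) / (10 + 2.0)
        assert np.allclose(model.foreground[:, 0], expected)
        with pytest.raises(ValueError, match="pseudocount"):
            pwm_model(counts, pseudocount=0.0)

    def test_agrees_with_order_one_markov(self):
        # a PWM is a context-free Markov motif: identical tail probabilities
        rng = np.random.default_rng(6)
        N = 4
        freqs = rng.dirichlet(np.full(4, 0.7), size=N).T
        bg = rng.dirichlet(np.full(4, 20.0))
        pwm = pwm_model(freqs, bg)
        chain = markov_model(
            1, 4, freqs[:, 0], [np.tile(freqs[:, i], (4, 1)) for i in range(1, N)],
            N, bg, [np.tile(bg, (4, 1))] * (N - 1))
        dist_a = enumerate_distribution(pwm.graph, pwm.score)
        dist_b = enumerate_distribution(chain.graph, chain.score)
        assert np.allclose(dist_a.support, dist_b.support, atol=1e-10)
        assert np.allclose(dist_a.probs, dist_b.probs, atol=1e-10)

    def test_window_scores_match_library_scoring(self):
        rng = np.random.default_rng(7)
        model = pwm_model(rng.dirichlet(np.ones(4), size=5).T)
        seqs = rng.integers(0, 4, (10, 9))
        ws = model.window_scores(seqs)
        assert ws.shape == (10, 5)
        from fgsig import sample_scores
        assert np.allclose(ws[:, 2], sample_scores(model.graph, model.score,
                                                   seqs[:, 2:7]), atol=1e-12)


class TestMarkovModel:
    @staticmethod
    def _random_chain(seed, r, L, conc_fg=0.6, conc_bg=8.0):
        rng = np.random.default_rng(seed)
        K = 4 ** r
        fg_init = rng.dirichlet(np.full(K, 1.0))
        bg_init = rng.dirichlet(np.full(K, conc_bg))
        fg_tr = [rng.dirichlet(np.full(4, conc_fg), size=K) for _ in range(L - r)]
        bg_tr = rng.dirichlet(np.full(4, conc_bg), size=K)
        return fg_init, fg_tr, bg_init, bg_tr

    def test_first_order_reduces_to_plain_chain(self):
        fg_init, fg_tr, bg_init, bg_tr = self._random_chain(8, 1, 5)
        model = markov_model(1, 4, fg_init, fg_tr, 5, bg_init, [bg_tr] * 4)
        seqs, p_bg = seq_brute_force(4, 1, 5, bg_init, [bg_tr] * 4)
        _, p_fg = seq_brute_force(4, 1, 5, fg_init, fg_tr)
        s = np.log(p_fg / p_bg)
        for t in np.quantile(s, [0.5, 0.9, 0.99]):
            assert np.isclose(enumerate_tail(model.graph, model.score, t),
                              p_bg[s > t].sum(), rtol=1e-10)

    def test_second_order_exact_tail(self):
        r, L = 2, 5
        fg_init, fg_tr, bg_init, bg_tr = self._random_chain(9, r, L)
        model = markov_model(r, 4, fg_init, fg_tr, L, bg_init, [bg_tr] * (L - r))
        assert is_normalized(model.graph, 1e-10)
        seqs, p_bg = seq_brute_force(4, r, L, bg_init, [bg_tr] * (L - r))
        _, p_fg = seq_brute_force(4, r, L, fg_init, fg_tr)
        s = np.log(p_fg / p_bg)
        for t in np.quantile(s, [0.5, 0.95, 0.999]):
            assert np.isclose(enumerate_tail(model.graph, model.score, t),
                              p_bg[s > t].sum(), rtol=1e-10)

    def test_second_order_cgf_matches_sequence_brute_force(self):
        r, L = 2, 8
        fg_init, fg_tr, bg_init, bg_tr = self._random_chain(10, r, L)
        model = markov_model(r, 4, fg_init, fg_tr, L, bg_init, [bg_tr] * (L - r))
        seqs, p_bg = seq_brute_force(4, r, L, bg_init, [bg_tr] * (L - r))
        _, p_fg = seq_brute_force(4, r, L, fg_init, fg_tr)
        s = np.log(p_fg / p_bg)
        for theta in (0.0, 0.7, -0.4):
            r_cgf = cgf_moments(model.graph, model.score, theta)
            phi = np.sum(p_bg * np.exp(theta * s))
            assert np.isclose(r_cgf.kappa, np.log(phi), rtol=1e-10, atol=1e-12)

    def test_dimension_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            markov_model(1, 4, np.full(4, 0.25), np.ones((4, 4)), 3,
                         np.full(4, 0.25), np.full((4, 4), 0.25))


class TestJukesCantor:
    def test_zero_branch_is_identity(self):
        assert np.allclose(jc69_transition(1.0, 0.0), np.eye(4))

    def test_long_branch_is_stationary(self):
        assert np.allclose(jc69_transition(1.0, 1e6), 0.25, atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            P = jc69_transition(rng.uniform(0.1, 3), rng.uniform(0.01, 5))
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(P > 0)

    def test_law_of_total_expectation(self):
        for mu, t in ((1.0, 0.3), (0.7, 2.1), (2.0, 0.05)):
            P = jc69_transition(mu, t)
            E = jc69_expected_substitutions(mu, t)
            assert np.allclose((P * E).sum(axis=1), mu * t, atol=1e-10)

    def test_identical_endpoints_still_expect_substitutions(self):
        for t in (0.05, 0.5, 3.0):
            E = jc69_expected_substitutions(1.0, t)
            assert np.all(np.diag(E) > 0)

    def test_matches_ctmc_simulation(self):
        mu, t = 1.0, 0.4
        E = jc69_expected_substitutions(mu, t)
        P = jc69_transition(mu, t)
        sim = simulate_ctmc(mu, t, start=0, n=300_000, seed=12)
        for b in range(4):
            assert abs(sim.endpoint_probs[b] - P[0, b]) < 4 * max(sim.endpoint_probs_se[b], 1e-4)
            assert abs(sim.mean_subs[b] - E[0, b]) < 3.5 * sim.mean_subs_se[b]

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            jc69_transition(1.0, -0.1)
        with pytest.raises(ValueError):
            jc69_expected_substitutions(1.0, 0.0)


class TestPhyloModel:
    def test_two_leaf_hand_enumeration(self):
        model = phylo_model("(A:0.1,B:0.2);")
        P1, P2 = jc69_transition(1.0, 0.1), jc69_transition(1.0, 0.2)
        E1, E2 = jc69_expected_substitutions(1.0, 0.1), jc69_expected_substitutions(1.0, 0.2)
        a, b = 0, 2
        w = np.array([0.25 * P1[r, a] * P2[r, b] for r in range(4)])
        expected = float(np.sum(w * np.array([E1[r, a] + E2[r, b] for r in range(4)])) / w.sum())
        got = float(model.expected_substitutions(
            np.array([[a, b]]) if model.leaf_names == ["A", "B"] else np.array([[b, a]]))[0])
        assert np.isclose(got, expected, rtol=1e-10)

    def test_identity_column_statistic_positive(self):
        model = phylo_model("((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.2);")
        stat = model.expected_substitutions(np.zeros((1, 4), dtype=int))[0]
        assert stat > 0.0

    def test_batch_matches_per_column_posterior(self):
        from fgsig import posterior_expected_score
        model = phylo_model("((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.2);")
        rng = np.random.default_rng(13)
        cols = rng.integers(0, 4, (20, 4))
        batch = model.expected_substitutions(cols)
        for i in range(20):
            per = posterior_expected_score(model.graph, model.score,
                                           model.column_evidence(cols[i]))
            assert np.isclose(batch[i], per, rtol=1e-10)

    def test_null_model_is_normalized(self):
        model = phylo_model("((A:0.1,B:0.2):0.15,C:0.3);")
        assert is_normalized(model.graph, 1e-10)

    def test_errors(self):
        with pytest.raises(ValueError, match="2 leaves"):
            phylo_model("(A:1.0);")
        with pytest.raises(ValueError, match="length"):
            phylo_model("(A:0.1,B);")


class TestMaxScorePvalue:
    def test_zero_probability(self):
        assert max_score_pvalue(0.0, 200, 16) == 0.0

    def test_small_mp_expansion(self):
        p, L, k = 1e-8, 200, 16
        M = L - k + 1
        assert np.isclose(max_score_pvalue(p, L, k), M * p, rtol=1e-4)

    def test_warns_when_mp_large(self):
        with pytest.warns(UserWarning, match="Poisson approximation"):
            max_score_pvalue(0.01, 200, 16)

    def test_validation(self):
        with pytest.raises(ValueError):
            max_score_pvalue(1.5, 200, 16)
        with pytest.raises(ValueError):
            max_score_pvalue(0.1, 10, 16)
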