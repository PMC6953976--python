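import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from netsi import (
    Graph,
    NetworkOrder,
    PaParams,
    attachment_weights,
    back_degrees,
    cpois_logpmf,
    cpois_sample,
    generate_pa_network,
    log_graph_given_order,
    mu_star,
    sample_attachment_set,
)
from netsi import _kernels
from netsi.pa import (
    _set_logprob_bruteforce,
    cpois_mean,
    enumerate_supported_graphs,
    log_graph_given_order_ref,
)


class TestCensoredPoisson:
    def test_mass_collapses_onto_one_as_mu_vanishes(self):
        assert math.isclose(math.exp(cpois_logpmf(1, 1e-12, 5)), 1.0, rel_tol=1e-9)
        assert cpois_logpmf(1, 0.0, 5) == 0.0

    def test_first_branch_value(self):
        # P(X=1) = e^-mu (1+mu): at mu=4 that is 5 e^-4
        assert math.isclose(
            math.exp(cpois_logpmf(1, 4.0, 10)), 5 * math.exp(-4), rel_tol=1e-12
        )

    def test_tail_branch_equals_complement(self):
        # at i=3 the support is {1,2}; the lumped tail is 1 - e^-2 (1+2)
        val = math.exp(cpois_logpmf(2, 2.0, 3))
        assert math.isclose(val, 1 - 3 * math.exp(-2), rel_tol=1e-12)
        # cross-check by summing the Poisson series
        series = sum(
            math.exp(-2) * 2.0**z / math.factorial(z) for z in range(2, 60)
        )
        assert math.isclose(val, series, rel_tol=1e-12)

    @pytest.mark.parametrize("mu", [0.3, 2.0, 6.0, 10.0])
    @pytest.mark.parametrize("i", [3, 5, 12, 40])
    def test_pmf_sums_to_one(self, mu, i):
        total = sum(math.exp(cpois_logpmf(x, mu, i)) for x in range(1, i))
        assert math.isclose(total, 1.0, rel_tol=1e-12)

    def test_pmf_at_one_decreasing_in_mu(self):
        vals = [math.exp(cpois_logpmf(1, mu, 20)) for mu in (0.5, 1, 2, 4, 8)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_outside_support_and_errors(self):
        assert cpois_logpmf(0, 2.0, 5) == -np.inf
        assert cpois_logpmf(5, 2.0, 5) == -np.inf
        with pytest.raises(ValueError):
            cpois_logpmf(1.5, 2.0, 5)
        with pytest.raises(ValueError):
            cpois_logpmf(1, -1.0, 5)

    def test_sample_support_censoring(self, rng):
        draws = {cpois_sample(6.0, 3, rng) for _ in range(300)}
        assert draws <= {1, 2}

    def test_sample_mean_matches_exact_mean(self, rng):
        draws = np.array([cpois_sample(6.0, 50, rng) for _ in range(10_000)])
        exact = cpois_mean(6.0, 50)
        assert math.isclose(exact, 6 + math.exp(-6), rel_tol=1e-4)
        assert abs(draws.mean() - exact) < 4 * draws.std() / 100  # 4 MC SE

    def test_sample_frequency_of_one(self, rng):
        draws = np.array([cpois_sample(0.3, 40, rng) for _ in range(10_000)])
        p1 = math.exp(-0.3) * 1.3
        freq = (draws == 1).mean()
        assert abs(freq - p1) < 4 * math.sqrt(p1 * (1 - p1) / 10_000)


class TestAttachmentWeights:
    @pytest.mark.parametrize(
        "degrees, gamma, expected",
        [
            ((1, 1), 0.0, (0.5, 0.5)),
            ((1, 1), 1.0, (1 / 3, 2 / 3)),
            ((2, 1, 1), 0.0, (0.5, 0.25, 0.25)),
        ],
    )
    def test_examples(self, degrees, gamma, expected):
        w = attachment_weights(np.array(degrees, dtype=float), gamma)
        np.testing.assert_allclose(w, expected, rtol=1e-12)

    @given(
        st.lists(st.integers(min_value=0, max_value=9), min_size=2, max_size=8).filter(
            lambda d: sum(d) > 0
        ),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_always_a_distribution(self, degrees, gamma):
        w = attachment_weights(np.array(degrees, dtype=float), gamma)
        assert math.isclose(w.sum(), 1.0, rel_tol=1e-9)
        assert (w >= 0).all()

    def test_zero_degrees_error(self):
        with pytest.raises(ValueError):
            attachment_weights(np.zeros(3), 0.0)


class TestSampleAttachmentSet:
    def test_full_set_certain(self, rng):
        got = sample_attachment_set(np.array([0.2, 0.3, 0.5]), 3, rng)
        assert sorted(got) == [0, 1, 2]

    def test_symmetric_two_weights(self, rng):
        hits = sum(
            sample_attachment_set(np.array([0.5, 0.5]), 1, rng)[0] == 0
            for _ in range(10_000)
        )
        assert abs(hits / 10_000 - 0.5) < 0.02

    def test_pair_frequencies_match_order_sum(self, rng):
        # brute-force oracle: P({a,b}) summed over both draw orders
        w = np.array([0.7, 0.2, 0.1])
        expected = {}
        for pair in itertools.combinations(range(3), 2):
            expected[pair] = math.exp(_set_logprob_bruteforce(w, list(pair)))
        n = 20_000
        counts = {pair: 0 for pair in expected}
        for _ in range(n):
            got = tuple(sorted(sample_attachment_set(w, 2, rng)))
            counts[got] += 1
        for pair, p in expected.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[pair] / n - p) < 4 * se

    def test_too_many_requested(self, rng):
        with pytest.raises(ValueError):
            sample_attachment_set(np.array([0.5, 0.5]), 3, rng)


class TestSetProbabilityKernels:
    @given(
        st.integers(min_value=2, max_value=6),
        st.lists(st.floats(min_value=0.05, max_value=1.0), min_size=7, max_size=9),
    )
    def test_dp_matches_bruteforce(self, x, raw):
        w = np.array(raw)
        w = w / w.sum()
        wc = np.sort(w[:x])[::-1].copy()
        dp = _kernels.set_logprob_dp(wc)
        bf = _set_logprob_bruteforce(w, list(range(x)))
        assert math.isclose(dp, bf, rel_tol=1e-10, abs_tol=1e-10)

    def test_dp_handles_tied_weights(self):
        w = np.array([0.1, 0.1, 0.1, 0.05, 0.05, 0.6])
        wc = np.sort(w[:5])[::-1].copy()
        dp = _kernels.set_logprob_dp(wc)
        bf = _set_logprob_bruteforce(w, list(range(5)))
        assert math.isclose(dp, bf, rel_tol=1e-10)

    @pytest.mark.parametrize("x", [8, 11, 14])
    def test_quadrature_matches_dp(self, x):
        rng = np.random.default_rng(x)
        w = rng.dirichlet(np.ones(40))
        wc = np.sort(w[:x])[::-1].copy()
        dp = _kernels.set_logprob_dp(wc.copy())
        quad = _kernels.set_logprob_quad(wc.copy())
        assert math.isclose(dp, quad, rel_tol=1e-8, abs_tol=1e-8)

    def test_complete_selection_is_certain(self):
        # choosing every available node has probability 1
        wc = np.array([0.6, 0.4])
        assert _kernels.set_logprob(wc) == pytest.approx(0.0, abs=1e-12)


class TestGeneratePaNetwork:
    def test_two_nodes(self, rng):
        g, order = generate_pa_network(2, PaParams(3.0), rng)
        assert g.edge_count == 1

    def test_too_small(self, rng):
        with pytest.raises(ValueError):
            generate_pa_network(1, PaParams(3.0), rng)

    @pytest.mark.parametrize("gamma", [0.0, 0.6])
    def test_connected_and_supported(self, gamma, rng):
        for _ in range(20):
            g, order = generate_pa_network(15, PaParams(2.5, gamma), rng)
            assert g.is_connected()
            x = back_degrees(g, order)
            assert x[0] == 1
            assert (x[1:] >= 1).all()

    def test_mean_edge_count_matches_expectation(self, rng):
        # |G| = 1 + sum_{i=3}^m X_i with X_i censored Poisson
        m, mu = 70, 6.0
        expected = 1 + sum(cpois_mean(mu, i) for i in range(3, m + 1))
        sizes = [
            generate_pa_network(m, PaParams(mu), rng)[0].edge_count
            for _ in range(200)
        ]
        se = np.std(sizes) / math.sqrt(len(sizes))
        assert abs(np.mean(sizes) - expected) < 4 * se

    def test_recency_mixture_reduces_degree_inequality(self, rng):
        # gamma = 1 spreads attachments toward recent entrants, so degree
        # inequality (Gini) drops relative to pure preferential attachment
        def gini(degrees):
            d = np.sort(np.asarray(degrees, dtype=float))
            n = d.size
            return float(
                (2 * np.arange(1, n + 1) - n - 1).dot(d) / (n * d.sum())
            )

        g0 = []
        g1 = []
        for _ in range(40):
            ga, _ = generate_pa_network(120, PaParams(4.0, 0.0), rng)
            gb, _ = generate_pa_network(120, PaParams(4.0, 1.0), rng)
            g0.append(gini(ga.adj.sum(axis=0)))
            g1.append(gini(gb.adj.sum(axis=0)))
        assert np.mean(g1) < np.mean(g0)

    def test_fixed_order_respected(self, rng):
        order = NetworkOrder((3, 1, 2, 4))
        g, got = generate_pa_network(4, PaParams(2.0), rng, order=order)
        assert got == order
        assert g.has_edge(3, 1)  # founding dyad


class TestGraphDensity:
    def test_three_node_hand_values(self):
        mu = 1.7
        order = NetworkOrder.identity(3)
        params = PaParams(mu, 0.0)
        # node 3 attaches once, to node 1 (weights 1/2, 1/2)
        g = Graph.from_edges(3, [(1, 2), (1, 3)])
        expect = math.log(math.exp(-mu) * (1 + mu) * 0.5)
        assert math.isclose(log_graph_given_order(g, order, params), expect, rel_tol=1e-12)
        # complete graph: both nodes chosen, selection certain
        g = Graph.complete(3)
        expect = math.log(1 - math.exp(-mu) * (1 + mu))
        assert math.isclose(log_graph_given_order(g, order, params), expect, rel_tol=1e-12)

    def test_off_support_is_minus_inf(self):
        order = NetworkOrder.identity(3)
        g = Graph.from_edges(3, [(1, 3), (2, 3)])  # dyad edge (1,2) missing
        assert log_graph_given_order(g, order, PaParams(2.0)) == -np.inf

    @pytest.mark.parametrize("m", [3, 4])
    @pytest.mark.parametrize("gamma", [0.0, 0.5, 1.0])
    @pytest.mark.parametrize("mu", [0.5, 6.0])
    def test_normalisation(self, m, gamma, mu):
        order = NetworkOrder.identity(m)
        params = PaParams(mu, gamma)
        total = sum(
            math.exp(log_graph_given_order(g, order, params))
            for g in enumerate_supported_graphs(m, order)
        )
        assert abs(total - 1.0) < 1e-10

    @pytest.mark.parametrize("gamma", [0.0, 0.7])
    def test_kernel_matches_reference(self, gamma, rng):
        params = PaParams(1.8, gamma)
        for _ in range(8):
            g, order = generate_pa_network(9, params, rng)
            a = log_graph_given_order(g, order, params)
            b = log_graph_given_order_ref(g, order, params)
            assert math.isclose(a, b, rel_tol=1e-9)

    def test_simulator_frequencies_match_density(self, rng):
        # m=3, fixed order: three supported graphs; empirical frequencies
        # from the generator agree with the exact density
        m, params = 3, PaParams(1.2, 0.3)
        order = NetworkOrder.identity(m)
        graphs = list(enumerate_supported_graphs(m, order))
        probs = [math.exp(log_graph_given_order(g, order, params)) for g in graphs]
        n = 100_000
        counts = dict.fromkeys(range(len(graphs)), 0)
        for _ in range(n):
            g, _ = generate_pa_network(m, params, rng, order=order)
            for k, gg in enumerate(graphs):
                if gg == g:
                    counts[k] += 1
                    break
        for k, p in enumerate(probs):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[k] / n - p) < 4 * se


class TestMuStar:
    def test_values(self):
        assert mu_star(0.0) == 1.0
        assert math.isclose(mu_star(6.0), 6.002478752, rel_tol=1e-9)
        assert round(0.4 * mu_star(6.0), 3) == 2.401

    def test_minimum_at_zero(self):
        grid = np.linspace(0.0, 5.0, 200)
        vals = [mu_star(v) for v in grid]
        assert min(vals) >= 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mu_star(-0.1)


class TestPaParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            PaParams(0.0)
        with pytest.raises(ValueError):
            PaParams(1.0, 1.5)
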