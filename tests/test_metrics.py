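"""Graph metrics, NTE censuses, Poisson GLM, perturbation census."""

import itertools

import numpy as np
import pandas as pd
import pytest

from timweb import TIM, TIMSet
from timweb import metrics
from timweb.webgen import FoodWeb


def make_web(S, links):
    links = list(links)
    return FoodWeb(
        S=S,
        consumers=np.array([c for c, _ in links], dtype=np.int64),
        resources=np.array([r for _, r in links], dtype=np.int64),
        niche_values=np.linspace(0, 1, S),
        target_C=0.1,
    )


def bfs_distance_oracle(S, undirected_edges, s, t):
    if s == t:
        return 0
    adj = {i: set() for i in range(S)}
    for a, b in undirected_edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, frontier, d = {s}, {s}, 0
    while frontier:
        d += 1
        frontier = {n for f in frontier for n in adj[f]} - seen
        if t in frontier:
            return d
        seen |= frontier
    return -1


class TestTrophicDistance:
    def test_direct_prey_and_self(self):
        web = make_web(3, [(1, 0), (2, 1)])
        assert metrics.trophic_distance(web, 1, 0) == 1
        assert metrics.trophic_distance(web, 2, 2) == 0
        assert metrics.trophic_distance(web, 2, 0) == 2

    def test_disconnected_sentinel(self):
        web = make_web(4, [(1, 0), (3, 2)])
        assert metrics.trophic_distance(web, 0, 2) == -1

    def test_random_graphs_match_bfs_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 7))
            pairs = [(c, r) for c in range(n) for r in range(n) if c != r]
            mask = rng.uniform(size=len(pairs)) < 0.3
            links = [p for p, keep in zip(pairs, mask) if keep]
            web = make_web(n, links)
            s, t = rng.integers(n, size=2)
            assert metrics.trophic_distance(web, int(s), int(t)) == \
                bfs_distance_oracle(n, links, int(s), int(t))


class TestMeanPathLength:
    def test_complete_graph(self):
        links = [(c, r) for c in range(4) for r in range(4) if c > r]
        assert metrics.mean_path_length(make_web(4, links)) == pytest.approx(1.0)

    def test_three_chain(self):
        # distances 1, 1, 2 over three unordered pairs -> 4/3
        web = make_web(3, [(1, 0), (2, 1)])
        assert metrics.mean_path_length(web) == pytest.approx(4 / 3)

    def test_exhaustive_small_graphs_match_oracle(self):
        n = 4
        pairs = [(c, r) for c in range(n) for r in range(n) if c > r]
        for bits in range(2 ** len(pairs)):
            links = [p for i, p in enumerate(pairs) if bits >> i & 1]
            web = make_web(n, links)
            dists = [
                bfs_distance_oracle(n, links, s, t)
                for s, t in itertools.combinations(range(n), 2)
            ]
            if any(d == -1 for d in dists):
                assert metrics.mean_path_length(web) == float("inf")
            else:
                assert metrics.mean_path_length(web) == pytest.approx(
                    np.mean(dists))

    def test_tim_edges_shorten_paths(self):
        # 5-chain; a TIM whose modifier (4) touches link (0,1) adds
        # shortcuts 4-0 and 4-1
        web = make_web(5, [(1, 0), (2, 1), (3, 2), (4, 3)])
        base = metrics.mean_path_length(web)
        tims = TIMSet(
            resource=np.array([0]), consumer=np.array([1]),
            modifier=np.array([4]), alpha=np.array([1.0]),
            tau=np.array([0.0]), sigma=np.array([1.0]),
            Bk_star=np.array([1.0]), link_index=np.array([0]),
        )
        with_tims = metrics.mean_path_length(web, tims)
        # oracle: recompute on the augmented edge set
        edges = [(1, 0), (2, 1), (3, 2), (4, 3), (4, 0), (4, 1)]
        expect = np.mean([
            bfs_distance_oracle(5, edges, s, t)
            for s, t in itertools.combinations(range(5), 2)
        ])
        assert with_tims == pytest.approx(expect)
        assert with_tims < base


class TestExpectedIncomingNtes:
    def test_no_links_zero(self):
        web = make_web(3, [(1, 0)])
        assert metrics.expected_incoming_ntes(2, web, 0.1)["total"] == 0.0

    def test_enumeration_oracle(self):
        # species 0 participates in 2 links; each link has S-2=2
        # candidate modifiers -> 4 combinations at probability p
        web = make_web(4, [(1, 0), (2, 0)])
        out = metrics.expected_incoming_ntes(0, web, 0.25)
        assert out["total"] == pytest.approx(4 * 0.25)
        assert out["beneficial"] == pytest.approx(0.5 * out["total"])

    def test_linear_in_rate(self):
        web = make_web(5, [(1, 0), (2, 1), (3, 1)])
        full = metrics.expected_incoming_ntes(1, web, 0.08)["total"]
        half = metrics.expected_incoming_ntes(1, web, 0.04)["total"]
        assert half == pytest.approx(full / 2)


class TestCountIncomingNtes:
    def make_tims(self):
        links_web = make_web(4, [(1, 0), (2, 1)])
        tims = [
            TIM(0, 1, 3, alpha=2.0, tau=0.1, sigma=1.0, Bk_star=1.0),
            TIM(1, 2, 3, alpha=-1.0, tau=0.1, sigma=1.0, Bk_star=1.0),
        ]
        from timweb.params import LinkParams
        lk = LinkParams(
            resource=np.array([0, 1]), consumer=np.array([1, 2]),
            a=np.ones(2), e=np.full(2, 0.1), omega=np.ones(2))
        return TIMSet.from_tims(tims, lk)

    def test_empty(self):
        out = metrics.count_incoming_ntes(0, TIMSet.empty())
        assert out.beneficial_in == out.detrimental_in == 0

    def test_sign_attribution(self):
        ts = self.make_tims()
        # species 1: consumer of facilitating TIM (beneficial) and
        # resource of interfering TIM (beneficial)
        out = metrics.count_incoming_ntes(1, ts)
        assert out.beneficial_in == 2 and out.detrimental_in == 0
        # species 0: resource of facilitating TIM -> detrimental
        out0 = metrics.count_incoming_ntes(0, ts)
        assert out0.detrimental_in == 1 and out0.beneficial_in == 0

    def test_target_scope_filter(self):
        ts = self.make_tims()
        out = metrics.count_incoming_ntes(
            1, ts, scope="from_target_only", target=2)
        assert out.total == 0
        out = metrics.count_incoming_ntes(
            1, ts, scope="from_target_only", target=3)
        assert out.total == 2


class TestFitExtinctionGlm:
    def test_parameter_recovery_on_synthetic_poisson(self, rng):
        # counts ~ Poisson(exp(b0 + b1*x)): recover b1 within 3 SE
        b0, b1 = 0.3, 0.12
        x = rng.integers(0, 12, size=4000)
        y = rng.poisson(np.exp(b0 + b1 * x))
        df = pd.DataFrame({"n_extinct": y, "n_tims_by_target": x})
        fit = metrics.fit_extinction_glm(df)
        est = fit.loc["n_tims_by_target"]
        assert abs(est.coef - b1) < 3 * est.se
        assert est.pct_per_tim == pytest.approx(
            100 * (np.exp(est.coef) - 1))

    def test_split_recovery(self, rng):
        b_int, b_fac = 0.10, 0.04
        xi = rng.integers(0, 8, size=6000)
        xf = rng.integers(0, 8, size=6000)
        y = rng.poisson(np.exp(0.2 + b_int * xi + b_fac * xf))
        df = pd.DataFrame({
            "n_extinct": y,
            "n_interfering_by_target": xi,
            "n_facilitating_by_target": xf,
        })
        fit = metrics.fit_extinction_glm(df, split_by_sign=True)
        assert abs(fit.loc["n_interfering_by_target"].coef - b_int) < 0.02
        assert abs(fit.loc["n_facilitating_by_target"].coef - b_fac) < 0.02

    def test_constant_response_flat_slope(self, rng):
        df = pd.DataFrame({
            "n_extinct": np.full(500, 3),
            "n_tims_by_target": rng.integers(0, 10, 500),
        })
        fit = metrics.fit_extinction_glm(df)
        assert abs(fit.loc["n_tims_by_target"].coef) < 1e-6

    def test_degenerate_predictor_raises(self):
        df = pd.DataFrame({"n_extinct": [1, 2], "n_tims_by_target": [3, 3]})
        with pytest.raises(ValueError):
            metrics.fit_extinction_glm(df)


class TestAttackRateChange:
    def test_vanishing_span_gives_unit_factor(self):
        ts = TIMSet(
            resource=np.array([0]), consumer=np.array([1]),
            modifier=np.array([2]), alpha=np.array([1.0]),
            tau=np.array([0.3]), sigma=np.array([1e-6]),
            Bk_star=np.array([1.0]), link_index=np.array([0]),
        )
        f = metrics.attack_rate_change_on_modifier_loss(ts)
        assert f[0] == pytest.approx(1.0, abs=1e-5)

    def test_factor_is_max_of_mu_and_inverse(self, rng):
        n = 50
        ts = TIMSet(
            resource=np.zeros(n, dtype=np.int64),
            consumer=np.ones(n, dtype=np.int64),
            modifier=np.full(n, 2, dtype=np.int64),
            alpha=rng.uniform(-3, 3, n), tau=rng.uniform(-0.9, 1, n),
            sigma=rng.uniform(0.1, 3, n),
            Bk_star=10.0 ** rng.uniform(-1, 1, n),
            link_index=np.zeros(n, dtype=np.int64),
        )
        factors = metrics.attack_rate_change_on_modifier_loss(ts)
        assert np.all(factors >= 1.0)
        from timweb.tims import log10_modification
        for i in range(n):
            mu0 = 10.0 ** float(log10_modification(
                0.0, ts.alpha[i], ts.tau[i], ts.sigma[i], ts.Bk_star[i]))
            assert factors[i] == pytest.approx(max(mu0, 1 / mu0), rel=1e-10)


class TestPerturbationCensus:
    def test_zero_delta_no_data(self, chain_community):
        out = metrics.perturbation_response_census(
            [chain_community], [TIMSet.empty()], delta=0.0, n_trials=20,
            rng=1)
        assert np.isnan(out)

    def test_three_species_chain_signs(self):
        """No-TIM chain at equilibrium: reducing the producer lowers the
        herbivore's growth and relieves the producer itself; the
        carnivore only responds to the herbivore (algebraic oracle)."""
        from timweb import integrate_to_steady_state, percapita_rates
        from conftest import make_chain_community
        com = make_chain_community()
        B, conv, _ = integrate_to_steady_state(
            np.array([5.0, 1.0, 0.5]), com.species, com.links)
        assert conv
        com.B_star = B
        base = percapita_rates(B, com.species, com.links)
        Bp = B.copy()
        Bp[0] *= 0.99
        resp = percapita_rates(Bp, com.species, com.links) - base
        assert resp[0] > 0      # self-regulation relief
        assert resp[1] < 0      # herbivore loses food
        assert resp[2] == pytest.approx(0.0, abs=1e-12)  # no direct link
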