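"""Post-hoc analyses of robustness suites.

Covers the structural statistics (trophic distances between target and
casualties, path lengths with and without TIM edges), the NTE-count
census around extinct species, Poisson regressions of extinction counts
on TIM authorship, the attack-rate change audit on modifier loss, and
the perturbation-response sign census.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dynamics import Community, percapita_rates
from .pairwise import nte_sign
from .tims import TIMSet, log10_modification
from .webgen import FoodWeb

__all__ = [
    "trophic_distance",
    "DistanceDistribution",
    "distance_distributions",
    "expected_incoming_ntes",
    "NTECountSummary",
    "count_incoming_ntes",
    "fit_extinction_glm",
    "mean_path_length",
    "attack_rate_change_on_modifier_loss",
    "perturbation_response_census",
]


def _undirected(web: FoodWeb) -> nx.Graph:
    return web.to_graph(directed=False)


def trophic_distance(web: FoodWeb, s: int, t: int) -> int:
    """Undirected shortest-path length between two species.

    Returns -1 for a disconnected pair (cannot occur in retained
    communities, which are connected by construction).
    """
    try:
        return int(nx.shortest_path_length(_undirected(web), s, t))
    except nx.NetworkXNoPath:
        return -1


@dataclass
class DistanceDistribution:
    """Pooled histograms of target->extinct and target->all distances."""

    observed: dict[int, int]
    baseline: dict[int, int]

    def observed_fraction(self, d: int) -> float:
        tot = sum(self.observed.values())
        return self.observed.get(d, 0) / tot if tot else float("nan")

    def baseline_fraction(self, d: int) -> float:
        tot = sum(self.baseline.values())
        return self.baseline.get(d, 0) / tot if tot else float("nan")

    def total_variation_from_baseline(self) -> float:
        """TV distance between the two normalized histograms."""
        ds = set(self.observed) | set(self.baseline)
        return 0.5 * sum(
            abs(self.observed_fraction(d) - self.baseline_fraction(d))
            for d in ds
        )


def distance_distributions(suite, mode: str = "none") -> DistanceDistribution:
    """Pool distance histograms over all completed tests of one mode.

    Observed counts distances from each target to its secondarily
    extinct species; the baseline counts distances from each target to
    every other species (so its total is ``sum(S - 1)`` over tests).
    Tests are pooled with equal weight.
    """
    observed: dict[int, int] = {}
    baseline: dict[int, int] = {}
    dist_cache: dict[int, dict] = {}
    for com in suite.communities.values():
        dist_cache[com.community_id] = dict(
            nx.all_pairs_shortest_path_length(_undirected(com.web))
        )
    sp = suite.species
    rows = sp[(sp["mode"] == mode) & sp.converged]
    for (cid, target), grp in rows.groupby(["community_id", "target"]):
        dists = dist_cache[cid][target]
        ext = grp.species[
            (grp.status == "extinct") & (grp.species != target)
        ]
        for s in ext:
            d = dists[s]
            observed[d] = observed.get(d, 0) + 1
        for s in dists:
            if s != target:
                d = dists[s]
                baseline[d] = baseline.get(d, 0) + 1
    return DistanceDistribution(observed=observed, baseline=baseline)


def expected_incoming_ntes(
    species: int, web: FoodWeb, rate: float,
    positive_alpha_mass: float = 0.5,
) -> dict[str, float]:
    """Expected incoming NTE counts for one species under random TIMs.

    A species taking part in ``d`` trophic links receives an NTE from
    every TIM on those links; each of the ``d * (S - 2)`` candidate
    (link, modifier) combinations exists with probability ``rate``.
    The expectation splits between beneficial and detrimental by the
    probability mass of the TIM slope's sign (0.5 for the symmetric
    alpha ranges used throughout).
    """
    d = int(np.sum(web.consumers == species) + np.sum(web.resources == species))
    total = d * (web.S - 2) * rate
    return {
        "total": total,
        "beneficial": total * positive_alpha_mass,
        "detrimental": total * (1.0 - positive_alpha_mass),
    }


@dataclass
class NTECountSummary:
    """Incoming NTE counts for one species, optionally target-filtered."""

    beneficial_in: int
    detrimental_in: int
    scope: str = "all_modifiers"

    @property
    def total(self) -> int:
        return self.beneficial_in + self.detrimental_in


def count_incoming_ntes(
    species: int,
    tims: TIMSet,
    scope: str = "all_modifiers",
    target: int | None = None,
) -> NTECountSummary:
    """Count beneficial/detrimental NTEs received by one species.

    Each TIM sends one NTE to its resource and one to its consumer;
    signs follow :func:`~timweb.pairwise.nte_sign`. With scope
    ``"from_target_only"`` only TIMs whose modifier is ``target`` count.
    """
    if scope not in ("all_modifiers", "from_target_only"):
        raise ValueError(f"unknown scope {scope!r}")
    ben = det = 0
    for tim in tims:
        if scope == "from_target_only" and tim.modifier != target:
            continue
        if species == tim.resource:
            role = "on_resource"
        elif species == tim.consumer:
            role = "on_consumer"
        else:
            continue
        sign = nte_sign(tim, role)
        if sign == "beneficial":
            ben += 1
        elif sign == "detrimental":
            det += 1
    return NTECountSummary(beneficial_in=ben, detrimental_in=det, scope=scope)


def fit_extinction_glm(
    tests: pd.DataFrame,
    split_by_sign: bool = False,
) -> pd.DataFrame:
    """Poisson regression of extinction counts on TIM authorship.

    Regresses ``n_extinct`` on ``n_tims_by_target`` (or, with
    ``split_by_sign``, on the interfering and facilitating counts) with
    a log link. The returned table reports, per predictor, the raw
    coefficient, its standard error, and ``100 * (exp(beta) - 1)`` —
    the percent change in expected extinctions per additional TIM.
    """
    cols = (["n_interfering_by_target", "n_facilitating_by_target"]
            if split_by_sign else ["n_tims_by_target"])
    data = tests[tests.converged] if "converged" in tests else tests
    for c in cols:
        if data[c].nunique() < 2:
            raise ValueError(f"predictor {c!r} has fewer than 2 levels")
    X = sm.add_constant(data[cols].astype(float))
    model = sm.GLM(data["n_extinct"].astype(float), X,
                   family=sm.families.Poisson())
    fit = model.fit()
    if not np.all(np.isfinite(fit.params)):
        raise RuntimeError("Poisson GLM did not converge to finite estimates")
    out = pd.DataFrame({
        "coef": fit.params,
        "se": fit.bse,
        "pvalue": fit.pvalues,
        "pct_per_tim": 100.0 * (np.exp(fit.params) - 1.0),
    })
    out.index.name = "term"
    return out


def mean_path_length(web: FoodWeb, tims: TIMSet | None = None) -> float:
    """Mean undirected shortest-path length over all species pairs.

    With a TIM set, the graph additionally contains undirected
    modifier-resource and modifier-consumer edges for every TIM (the
    modifier touches both trophic participants), capturing how TIMs
    shrink the network's effective distances. Returns ``inf`` for a
    disconnected graph.
    """
    g = _undirected(web)
    if tims is not None:
        for t in range(tims.n_tims):
            k = int(tims.modifier[t])
            g.add_edge(k, int(tims.resource[t]))
            g.add_edge(k, int(tims.consumer[t]))
    if not nx.is_connected(g):
        return float("inf")
    n = g.number_of_nodes()
    total = sum(
        d for _, row in nx.all_pairs_shortest_path_length(g) for d in row.values()
    )
    return total / (n * (n - 1))


def attack_rate_change_on_modifier_loss(tims: TIMSet) -> np.ndarray:
    """Fold change of each modified attack rate when its modifier dies.

    At the reference equilibrium ``mu = 1``; at ``Bk -> 0`` the Gompertz
    factor reaches its finite asymptote ``mu(0)``. Returns
    ``max(mu(0), 1/mu(0))`` per TIM, the multiplicative disturbance a
    modifier extinction inflicts on that attack rate.
    """
    if not tims.n_tims:
        return np.empty(0)
    lg0 = log10_modification(
        np.zeros(tims.n_tims), tims.alpha, tims.tau, tims.sigma, tims.Bk_star
    )
    return 10.0 ** np.abs(lg0)


def perturbation_response_census(
    communities: list[Community],
    tim_sets: list[TIMSet],
    delta: float = 0.01,
    n_trials: int = 100,
    rng: np.random.Generator | int | None = None,
    mode: str = "full",
    zero_tol: float = 1e-10,
) -> float:
    """Fraction of positive non-zero growth-rate responses to a pulse.

    Per trial, one randomly chosen species' density is reduced by a
    fraction ``delta`` from equilibrium and the per-capita growth-rate
    change of every *other* species (relative to the unperturbed state,
    which is zero up to integration residual) is evaluated; the
    perturbed species' own rate change is a mechanical consequence of
    its displacement, not a response, and is excluded. Responses with
    magnitude above ``zero_tol`` are pooled across trials and the
    positive fraction returned (NaN when nothing responds, e.g.
    ``delta = 0``).
    """
    gen = np.random.default_rng(rng)
    signs: list[np.ndarray] = []
    for com, tims in zip(communities, tim_sets):
        base = percapita_rates(
            com.B_star, com.species, com.links, tims, mode,
            B_star=com.B_star,
        )
        for _ in range(n_trials):
            k = int(gen.integers(com.S))
            B = com.B_star.copy()
            B[k] *= 1.0 - delta
            resp = percapita_rates(
                B, com.species, com.links, tims, mode, B_star=com.B_star,
            ) - base
            resp = np.delete(resp, k)
            nz = np.abs(resp) > zero_tol
            signs.append(resp[nz] > 0)
    if not signs or not sum(len(s) for s in signs):
        return float("nan")
    pooled = np.concatenate(signs)
    return float(np.mean(pooled))
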