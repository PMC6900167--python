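"""Niche-model food-web topology generation and structural analysis.

The niche model (Williams & Martinez 2000) places every species at a
uniform random position on a one-dimensional niche axis and assigns it a
feeding interval; a consumer eats every species whose niche value falls
inside its interval. It reproduces many regularities of empirical webs
(interval diets, realistic fractions of top/intermediate/basal species)
from just two inputs: species richness ``S`` and target connectance ``C``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "FoodWeb",
    "generate_niche_web",
    "trophic_levels",
    "is_connected",
    "realized_connectance",
]


@dataclass(frozen=True)
class FoodWeb:
    """A directed trophic topology.

    Links are directed consumer -> resource: ``(j, i)`` means species *j*
    eats species *i*. Cannibalistic (self) links are never present.

    Attributes
    ----------
    S : int
        Number of species (indexed ``0 .. S-1``).
    consumers, resources : ndarray of int
        Parallel arrays; link ``l`` is ``consumers[l] -> resources[l]``.
    niche_values : ndarray of float
        Niche-axis positions in [0, 1] (provenance of the topology).
    target_C : float
        The connectance the generator aimed for (links / S^2 convention).
    seed : int or None
        RNG seed the link set is reproducible from.
    """

    S: int
    consumers: np.ndarray
    resources: np.ndarray
    niche_values: np.ndarray
    target_C: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.consumers == self.resources):
            raise ValueError("cannibalistic links are not allowed")
        if self.n_links and (
            max(self.consumers.max(), self.resources.max()) >= self.S
        ):
            raise ValueError("link endpoint out of range")

    @property
    def n_links(self) -> int:
        return int(len(self.consumers))

    @property
    def link_set(self) -> set[tuple[int, int]]:
        """Links as a set of (consumer, resource) tuples."""
        return set(zip(self.consumers.tolist(), self.resources.tolist()))

    def resources_of(self, j: int) -> np.ndarray:
        """Indices of the species consumer ``j`` feeds on."""
        return self.resources[self.consumers == j]

    def consumers_of(self, i: int) -> np.ndarray:
        """Indices of the species that feed on ``i``."""
        return self.consumers[self.resources == i]

    def to_graph(self, directed: bool = True) -> "nx.Graph":
        """networkx view (directed consumer->resource, or undirected)."""
        g = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(range(self.S))
        g.add_edges_from(zip(self.consumers.tolist(), self.resources.tolist()))
        return g


def generate_niche_web(
    S: int,
    C: float,
    rng: np.random.Generator | int | None = None,
) -> FoodWeb:
    """Draw one niche-model web and strip cannibalistic links.

    Each species gets a niche value ``n_i ~ U(0,1)``, a feeding range
    ``r_i = n_i * x`` with ``x ~ Beta(1, 1/(2C) - 1)`` and a range centre
    ``c_i ~ U(r_i/2, n_i)``; *i* eats every *j* with ``n_j`` inside
    ``[c_i - r_i/2, c_i + r_i/2]``. Self-links are removed afterwards, so
    the realized link density sits slightly below the ``L = C*S^2`` the
    classical model targets.

    Parameters
    ----------
    S : int
        Species richness, at least 2.
    C : float
        Target connectance in (0, 0.5) under the ``L/S^2`` convention.
    rng : Generator, int seed, or None
        Passing an int stores it on the returned web for replay.
    """
    if S < 2:
        raise ValueError(f"need at least 2 species, got S={S}")
    beta_b = 1.0 / (2.0 * C) - 1.0
    if not (0.0 < C < 0.5) or beta_b <= 0:
        raise ValueError(f"connectance must satisfy 0 < C < 0.5, got C={C}")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng)

    n = gen.uniform(0.0, 1.0, size=S)
    x = gen.beta(1.0, beta_b, size=S)
    r = n * x
    c = gen.uniform(r / 2.0, n)

    lo = c - r / 2.0
    hi = c + r / 2.0
    # eats[j, i]: consumer j eats resource i
    eats = (n[None, :] >= lo[:, None]) & (n[None, :] <= hi[:, None])
    np.fill_diagonal(eats, False)
    consumers, resources = np.nonzero(eats)

    return FoodWeb(
        S=S,
        consumers=consumers.astype(np.int64),
        resources=resources.astype(np.int64),
        niche_values=n,
        target_C=float(C),
        seed=int(seed) if seed is not None else None,
    )


def trophic_levels(web: FoodWeb) -> np.ndarray:
    """Integer trophic levels from shortest chains to a producer.

    Producers (species with no resources) sit at level 1; every consumer
    sits at ``1 +`` the length of its shortest directed path (following
    consumer -> resource links) to any producer.

    Raises
    ------
    ValueError
        If some consumer has no path down to a producer (e.g. a detached
        feeding loop); such webs are rejected upstream.
    """
    has_resource = np.zeros(web.S, dtype=bool)
    has_resource[web.consumers] = True
    levels = np.zeros(web.S, dtype=np.int64)
    levels[~has_resource] = 1

    # BFS upwards from all producers along resource -> consumer edges.
    frontier = list(np.nonzero(~has_resource)[0])
    while frontier:
        nxt: list[int] = []
        for i in frontier:
            for j in web.consumers_of(int(i)):
                if levels[j] == 0:
                    levels[j] = levels[i] + 1
                    nxt.append(int(j))
        frontier = nxt
    if np.any(levels == 0):
        bad = np.nonzero(levels == 0)[0]
        raise ValueError(
            f"consumers with no directed path to a producer: {bad.tolist()}"
        )
    return levels


def is_connected(web: FoodWeb) -> bool:
    """True iff the undirected projection of the web is one component."""
    return nx.is_connected(web.to_graph(directed=False))


def realized_connectance(web: FoodWeb, directed_pairs: bool = True) -> float:
    """Realized link density.

    With ``directed_pairs`` (default) the denominator is ``S*(S-1)``,
    the number of possible non-cannibalistic directed links; otherwise
    the classical ``S^2``.
    """
    denom = web.S * (web.S - 1) if directed_pairs else web.S**2
    return web.n_links / denom
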