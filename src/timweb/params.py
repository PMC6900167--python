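"""Allometric parameterization of a generated web.

All rates follow quarter-power body-mass scaling (Yodzis & Innes style):
species draw a body mass from a trophic-level-dependent lognormal, and
metabolic loss and attack rates scale as ``M^-0.25``. Producers grow
logistically (r = 1, moderate self-regulation, K ~ U(1,10)); consumers
pay a metabolic cost ``r = -0.1 M^-0.25`` and carry only weak
self-regulation (K ~ 10^U(2,3), well above typical densities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .webgen import FoodWeb

__all__ = [
    "SpeciesParams",
    "LinkParams",
    "assign_body_masses",
    "assign_species_params",
    "assign_link_params",
]

#: mean log10 body-mass step per trophic level (consumer-resource mass
#: ratio 10^2) and its spread, used when no explicit values are given.
DEFAULT_LOG10_MASS_STEP = 2.0
DEFAULT_LOG10_MASS_SD = 0.5


@dataclass
class SpeciesParams:
    """Per-species parameter table (struct of arrays, one entry each).

    Attributes
    ----------
    M : ndarray
        Body mass (arbitrary units, > 0).
    r : ndarray
        Intrinsic growth (producers, +1) or metabolic loss rate
        (consumers, ``-0.1 M^-0.25`` < 0), per unit time.
    K : ndarray
        Carrying capacity (biomass-density units).
    m : ndarray
        External mortality, 0 at initialization; robustness tests set
        the targeted species' entry to 1.
    level : ndarray of int
        Shortest-chain trophic level (producers = 1).
    """

    M: np.ndarray
    r: np.ndarray
    K: np.ndarray
    m: np.ndarray
    level: np.ndarray

    @property
    def S(self) -> int:
        return int(len(self.M))

    def copy(self) -> "SpeciesParams":
        return SpeciesParams(
            self.M.copy(), self.r.copy(), self.K.copy(),
            self.m.copy(), self.level.copy(),
        )


@dataclass
class LinkParams:
    """Per-trophic-link parameter table (parallel arrays).

    Link ``l`` is consumer ``consumer[l]`` eating resource
    ``resource[l]`` with attack rate ``a = omega * M_consumer^-0.25``,
    assimilation efficiency ``e ~ U(0.05, 0.15)`` and generality weight
    ``omega = 1/n`` for a consumer with ``n`` resources. ``omega`` is
    fixed at assignment and never recalculated, even if resources are
    later lost.
    """

    resource: np.ndarray
    consumer: np.ndarray
    a: np.ndarray
    e: np.ndarray
    omega: np.ndarray

    @property
    def n_links(self) -> int:
        return int(len(self.resource))

    def copy(self) -> "LinkParams":
        return LinkParams(
            self.resource.copy(), self.consumer.copy(),
            self.a.copy(), self.e.copy(), self.omega.copy(),
        )


def assign_body_masses(
    levels: np.ndarray,
    rng: np.random.Generator | int | None = None,
    log10_step: float = DEFAULT_LOG10_MASS_STEP,
    log10_sd: float = DEFAULT_LOG10_MASS_SD,
) -> np.ndarray:
    """Draw body masses from a level-dependent lognormal.

    ``log10 M ~ Normal(log10_step * (level - 1), log10_sd)``: producers
    have median mass 1, each trophic level multiplies the median mass by
    ``10^log10_step`` (default 100, a standard consumer-resource mass
    ratio).
    """
    gen = np.random.default_rng(rng)
    levels = np.asarray(levels)
    mu = log10_step * (levels - 1.0)
    return 10.0 ** gen.normal(mu, log10_sd)


def assign_species_params(
    M: np.ndarray,
    levels: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> SpeciesParams:
    """Assign r, K and (zero) external mortality from masses and levels."""
    gen = np.random.default_rng(rng)
    M = np.asarray(M, dtype=float)
    levels = np.asarray(levels)
    producer = levels == 1

    r = np.where(producer, 1.0, -0.1 * M ** -0.25)
    K = np.where(
        producer,
        gen.uniform(1.0, 10.0, size=len(M)),
        10.0 ** gen.uniform(2.0, 3.0, size=len(M)),
    )
    m = np.zeros(len(M))
    return SpeciesParams(M=M.copy(), r=r, K=K, m=m, level=levels.copy())


def assign_link_params(
    web: FoodWeb,
    M: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> LinkParams:
    """Assign attack rates, efficiencies and generality weights per link.

    Raises
    ------
    ValueError
        If the web labels a species as consumer with zero resources
        (cannot happen for webs straight from the generator, where
        "consumer" is defined by having at least one resource).
    """
    gen = np.random.default_rng(rng)
    M = np.asarray(M, dtype=float)
    con = web.consumers.astype(np.int64)
    res = web.resources.astype(np.int64)
    if len(con) == 0:
        return LinkParams(
            resource=res, consumer=con,
            a=np.empty(0), e=np.empty(0), omega=np.empty(0),
        )
    n_resources = np.bincount(con, minlength=web.S)
    if np.any(n_resources[np.unique(con)] == 0):  # pragma: no cover
        raise ValueError("consumer with zero resources")
    omega = 1.0 / n_resources[con]
    a = omega * M[con] ** -0.25
    e = gen.uniform(0.05, 0.15, size=len(con))
    return LinkParams(resource=res, consumer=con, a=a, e=e, omega=omega)
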