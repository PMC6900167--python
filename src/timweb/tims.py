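"""Trophic interaction modifications (TIMs): the Gompertz modification
function, random TIM placement, and multiplicative combination.

A TIM is a third species *k* (the modifier) that rescales the attack
rate of consumer *j* on resource *i* by a positive factor
``mu_ijk(B_k)``. The factor follows a Gompertz sigmoid of the log10
divergence of the modifier's density from its reference (starting
equilibrium) density ``Bk*``, parameterized by three ecologically
meaningful controls:

``alpha``
    Maximum slope of ``log10 mu`` against ``x = log10(Bk / Bk*)``;
    positive for a *facilitating* TIM (more modifier, stronger
    interaction), negative for an *interfering* one.
``tau``
    Proportional change of the modifier from ``Bk*`` at which the
    response is steepest: the threshold sits at ``Bk = (1 + tau) Bk*``,
    i.e. at ``x_t = log10(1 + tau)`` on the log axis.
``sigma``
    Total span of ``log10 mu``: across all modifier densities the
    factor varies over exactly ``10^sigma``-fold.

The curve is anchored so that ``mu(Bk*) = 1``: trophic interaction
strengths at the starting equilibrium are taken to already include the
modifier's effect there. Writing ``g = e * alpha / sigma`` (which makes
the maximum log-slope exactly ``alpha``),

``log10 mu = sigma * exp(-exp(-g (x - x_t))) - sigma * exp(-exp(-g (0 - x_t)))``

Both asymptotes are finite, so a modifier crashing to zero density
leaves the interaction at a finite (possibly large) multiple of its
reference strength rather than diverging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .params import LinkParams

__all__ = [
    "TIM",
    "TIMSet",
    "modification_factor",
    "combined_modifier",
    "sample_tims",
    "expected_tim_count",
    "log10_modification",
    "log10_modification_slope",
]


class TIM(NamedTuple):
    """A single modification of link (resource, consumer) by modifier."""

    resource: int
    consumer: int
    modifier: int
    alpha: float
    tau: float
    sigma: float
    Bk_star: float


def _validate_shape(sigma, Bk_star) -> None:
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma (modification span) must be > 0")
    if np.any(np.asarray(Bk_star) <= 0):
        raise ValueError("Bk_star (reference density) must be > 0")


def log10_modification(Bk, alpha, tau, sigma, Bk_star):
    """``log10 mu_ijk`` for modifier density ``Bk`` (vectorized).

    ``Bk = 0`` evaluates the finite limiting asymptote; ``alpha = 0``
    degenerates continuously to ``mu = 1``.
    """
    _validate_shape(sigma, Bk_star)
    Bk = np.asarray(Bk, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    tau = np.asarray(tau, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(tau <= -1.0):
        raise ValueError("tau (proportional change to threshold) must be > -1")
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        x = np.log10(Bk / Bk_star)          # -inf at Bk = 0
        x_t = np.log10(1.0 + tau)
        g = np.e * alpha / sigma
        arg = -g * (x - x_t)
        # exp(-exp(arg)): overflow in the inner exp is benign (-> 0)
        rise = np.exp(-np.exp(arg))
        anchor = np.exp(-np.exp(g * x_t))
        out = sigma * (rise - anchor)
    # Bk = 0 with g > 0: arg = +inf -> rise = 0 (numpy yields it); with
    # g < 0: arg = -inf -> rise = 1. alpha == 0 -> g = 0 -> rise==anchor.
    out = np.where(alpha == 0.0, 0.0, out)
    return out


def log10_modification_slope(Bk, alpha, tau, sigma, Bk_star):
    """``d(log10 mu)/dx`` at ``x = log10(Bk/Bk*)`` (for Jacobians).

    Tends to 0 double-exponentially in both tails; defined as 0 at
    ``Bk = 0`` and for ``alpha = 0``.
    """
    _validate_shape(sigma, Bk_star)
    Bk = np.asarray(Bk, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    tau = np.asarray(tau, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        x = np.log10(Bk / Bk_star)
        x_t = np.log10(1.0 + tau)
        g = np.e * alpha / sigma
        arg = -g * (x - x_t)
        slope = sigma * g * np.exp(arg - np.exp(arg))
    slope = np.where((alpha == 0.0) | ~np.isfinite(slope), 0.0, slope)
    # inner exp overflow -> exp(arg - exp(arg)) underflows to 0 correctly,
    # but arg = +/-inf produces nan via inf - inf; both tails are flat.
    bad = ~np.isfinite(np.asarray(arg))
    slope = np.where(bad, 0.0, slope)
    return slope


def modification_factor(Bk, tim: TIM):
    """Evaluate ``mu_ijk(Bk) > 0`` for one TIM (scalar or array ``Bk``)."""
    lg = log10_modification(Bk, tim.alpha, tim.tau, tim.sigma, tim.Bk_star)
    return 10.0 ** lg


@dataclass
class TIMSet:
    """A collection of TIMs over one community's trophic links.

    Stored as parallel arrays; ``link_index[t]`` points into the
    community's :class:`~timweb.params.LinkParams` arrays so dynamics can
    accumulate per-link products cheaply.
    """

    resource: np.ndarray
    consumer: np.ndarray
    modifier: np.ndarray
    alpha: np.ndarray
    tau: np.ndarray
    sigma: np.ndarray
    Bk_star: np.ndarray
    link_index: np.ndarray
    max_per_interaction: int | None = None

    def __post_init__(self) -> None:
        if self.n_tims:
            same = (
                (self.resource == self.consumer)
                | (self.resource == self.modifier)
                | (self.consumer == self.modifier)
            )
            if np.any(same):
                raise ValueError("TIM species (i, j, k) must be distinct")
            _validate_shape(self.sigma, self.Bk_star)
            if self.max_per_interaction == 1 and (
                len(np.unique(self.link_index)) != self.n_tims
            ):
                raise ValueError(
                    "max_per_interaction=1 but a link carries several TIMs"
                )

    @property
    def n_tims(self) -> int:
        return int(len(self.resource))

    def __len__(self) -> int:
        return self.n_tims

    def __iter__(self):
        for t in range(self.n_tims):
            yield TIM(
                int(self.resource[t]), int(self.consumer[t]),
                int(self.modifier[t]), float(self.alpha[t]),
                float(self.tau[t]), float(self.sigma[t]),
                float(self.Bk_star[t]),
            )

    @classmethod
    def empty(cls) -> "TIMSet":
        z = np.empty(0, dtype=np.int64)
        f = np.empty(0, dtype=float)
        return cls(z, z.copy(), z.copy(), f, f.copy(), f.copy(), f.copy(),
                   z.copy())

    @classmethod
    def from_tims(
        cls,
        tims: list[TIM],
        links: LinkParams,
        max_per_interaction: int | None = None,
    ) -> "TIMSet":
        """Build a set from explicit TIMs, resolving link indices."""
        if not tims:
            return cls.empty()
        key = {
            (int(r), int(c)): l
            for l, (r, c) in enumerate(zip(links.resource, links.consumer))
        }
        idx = []
        for t in tims:
            if (t.resource, t.consumer) not in key:
                raise ValueError(
                    f"({t.resource}, {t.consumer}) is not an extant trophic link"
                )
            idx.append(key[(t.resource, t.consumer)])
        return cls(
            resource=np.array([t.resource for t in tims], dtype=np.int64),
            consumer=np.array([t.consumer for t in tims], dtype=np.int64),
            modifier=np.array([t.modifier for t in tims], dtype=np.int64),
            alpha=np.array([t.alpha for t in tims], dtype=float),
            tau=np.array([t.tau for t in tims], dtype=float),
            sigma=np.array([t.sigma for t in tims], dtype=float),
            Bk_star=np.array([t.Bk_star for t in tims], dtype=float),
            link_index=np.array(idx, dtype=np.int64),
            max_per_interaction=max_per_interaction,
        )

    def log10_mu(self, B: np.ndarray) -> np.ndarray:
        """Per-TIM ``log10 mu`` at the current biomass vector."""
        if not self.n_tims:
            return np.empty(0)
        return log10_modification(
            B[self.modifier], self.alpha, self.tau, self.sigma, self.Bk_star
        )

    def link_log10_mu(self, B: np.ndarray, n_links: int) -> np.ndarray:
        """Per-link ``log10 mu_ij`` (sums of TIM contributions)."""
        out = np.zeros(n_links)
        if self.n_tims:
            np.add.at(out, self.link_index, self.log10_mu(B))
        return out


def combined_modifier(link: tuple[int, int], B: np.ndarray, tims: TIMSet) -> float:
    """``mu_ij``: multiplicative combination of all TIMs on one link.

    Multiple modifiers of the same interaction act synergistically:
    ``mu_ij = prod_k mu_ijk``. Empty product -> 1.
    """
    i, j = link
    total = 0.0
    for t in range(tims.n_tims):
        if tims.resource[t] == i and tims.consumer[t] == j:
            total += float(
                log10_modification(
                    B[tims.modifier[t]], tims.alpha[t], tims.tau[t],
                    tims.sigma[t], tims.Bk_star[t],
                )
            )
    return 10.0 ** total


def sample_tims(
    links: LinkParams,
    B_star: np.ndarray,
    S: int,
    rate: float,
    alpha_range: tuple[float, float],
    sigma_range: tuple[float, float],
    tau_range: tuple[float, float],
    max_per_interaction: int | None,
    rng: np.random.Generator | int | None = None,
) -> TIMSet:
    """Place TIMs by independent Bernoulli trials per (link, modifier).

    Every combination of an extant trophic link (i, j) and a candidate
    modifier ``k not in {i, j}`` exists with probability ``rate``. Shape
    parameters are drawn uniformly from the given ranges and the
    modifier's reference density is its current equilibrium density
    ``B_star[k]``. With ``max_per_interaction = 1``, links that drew
    several TIMs keep one chosen uniformly at random.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    gen = np.random.default_rng(rng)
    L = links.n_links
    if L == 0 or rate == 0.0:
        return TIMSet.empty()

    # candidate matrix: L x S Bernoulli trials, excluding k in {i, j}
    trials = gen.uniform(size=(L, S)) < rate
    trials[np.arange(L), links.resource] = False
    trials[np.arange(L), links.consumer] = False
    link_idx, modifier = np.nonzero(trials)

    if max_per_interaction == 1 and len(link_idx):
        keep = np.zeros(len(link_idx), dtype=bool)
        for l in np.unique(link_idx):
            where = np.nonzero(link_idx == l)[0]
            keep[gen.choice(where)] = True
        link_idx, modifier = link_idx[keep], modifier[keep]

    n = len(link_idx)
    return TIMSet(
        resource=links.resource[link_idx].astype(np.int64),
        consumer=links.consumer[link_idx].astype(np.int64),
        modifier=modifier.astype(np.int64),
        alpha=gen.uniform(*alpha_range, size=n),
        tau=gen.uniform(*tau_range, size=n),
        sigma=gen.uniform(*sigma_range, size=n),
        Bk_star=np.asarray(B_star, dtype=float)[modifier],
        link_index=link_idx.astype(np.int64),
        max_per_interaction=max_per_interaction,
    )


def expected_tim_count(S: int, C: float, rate: float) -> float:
    """Expected TIM count ``C*S*(S-1) * rate * (S-2)``.

    ``C*S*(S-1)`` is the expected number of directed non-cannibalistic
    trophic links and each link has ``S-2`` candidate modifiers, each
    present with probability ``rate`` (no per-link cap applied).
    """
    return C * S * (S - 1) * rate * (S - 2)
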