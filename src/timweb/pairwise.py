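"""Partition of TIMs into equivalent pairwise non-trophic effects.

A modified trophic flow ``mu_ijk a_ij B_i B_j`` can be split into a plain
trophic part and a non-trophic remainder by freezing the trophic partner
at its starting-equilibrium density. On the resource's per-capita rate,

``- mu_ijk a_ij B_j  =  - a_ij B_j  +  a_ij Bj* (1 - mu_ijk)``

holds exactly at ``B_j = Bj*``, and symmetrically for the consumer with
coefficient ``e_ij a_ij Bi*``. The pairwise NTE keeps the equality on the
reference manifold but is independent of the partner's live density — in
particular it *persists unchanged after the trophic partner (or the
mechanism itself) is gone*, which is exactly where the two
representations diverge dynamically.

The partition is only well defined when each trophic link carries at
most one modifier, because multiple modifiers combine multiplicatively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .params import LinkParams
from .tims import TIM, TIMSet, log10_modification

__all__ = ["PairwiseNTE", "partition_tims", "nte_sign"]

Role = Literal["on_resource", "on_consumer"]


@dataclass(frozen=True)
class PairwiseNTE:
    """One pairwise non-trophic effect derived from a TIM.

    ``coefficient`` is the frozen positive constant (``a_ij * Bj*`` for
    the effect on the resource, ``e_ij a_ij Bi*`` for the effect on the
    consumer); the live per-capita contribution is
    ``coefficient * (1 - mu_ijk)`` on the resource and
    ``coefficient * (mu_ijk - 1)`` on the consumer, with ``mu_ijk``
    evaluated from the modifier's density only.
    """

    source: int
    target: int
    coefficient: float
    role: Role
    tim: TIM

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("NTE coefficient must be > 0")
        expected = self.tim.resource if self.role == "on_resource" \
            else self.tim.consumer
        if self.target != expected or self.source != self.tim.modifier:
            raise ValueError("NTE endpoints inconsistent with its TIM")

    def contribution(self, Bk: float) -> float:
        """Per-capita rate contribution at modifier density ``Bk``."""
        mu = 10.0 ** float(log10_modification(
            Bk, self.tim.alpha, self.tim.tau, self.tim.sigma, self.tim.Bk_star
        ))
        sign = 1.0 if self.role == "on_consumer" else -1.0
        return sign * self.coefficient * (mu - 1.0)

    @property
    def sign(self) -> str:
        return nte_sign(self.tim, self.role)


def partition_tims(
    tims: TIMSet,
    B_star: np.ndarray,
    links: LinkParams,
) -> list[PairwiseNTE]:
    """Two pairwise NTEs per TIM, coefficients frozen at ``B_star``.

    Raises
    ------
    ValueError
        If some trophic link carries more than one TIM (the synergistic
        multi-modifier combination cannot be partitioned pairwise).
    """
    if tims.n_tims and len(np.unique(tims.link_index)) != tims.n_tims:
        raise ValueError(
            "pairwise partition requires at most one modifier per link"
        )
    ntes: list[PairwiseNTE] = []
    for t, tim in enumerate(tims):
        li = int(tims.link_index[t])
        a, e = float(links.a[li]), float(links.e[li])
        ntes.append(PairwiseNTE(
            source=tim.modifier, target=tim.resource,
            coefficient=a * float(B_star[tim.consumer]),
            role="on_resource", tim=tim,
        ))
        ntes.append(PairwiseNTE(
            source=tim.modifier, target=tim.consumer,
            coefficient=e * a * float(B_star[tim.resource]),
            role="on_consumer", tim=tim,
        ))
    return ntes


def nte_sign(tim: TIM, role: Role) -> str:
    """Classify an NTE as beneficial or detrimental to its target.

    Signs follow the immediate impact of a modifier *increase*: a
    facilitating TIM (``alpha > 0``) strengthens consumption, so it is
    beneficial to the consumer and detrimental to the resource; an
    interfering TIM reverses both. ``alpha = 0`` is a null modification
    (excluded from counts).
    """
    if role not in ("on_resource", "on_consumer"):
        raise ValueError(f"unknown role {role!r}")
    if tim.alpha == 0:
        return "null"
    facilitating = tim.alpha > 0
    if role == "on_consumer":
        return "beneficial" if facilitating else "detrimental"
    return "detrimental" if facilitating else "beneficial"
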