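"""Bioenergetic Lotka-Volterra dynamics and steady-state integration.

Per-capita dynamics of species *i* (Holling type I / linear functional
response, logistic self-regulation):

``(1/Bi) dBi/dt = r_i - m_i - B_i/K_i
- sum_{j in consumers of i} mu_ij a_ij B_j
+ sum_{l in resources of i} mu_li e_li a_li B_l``

with three interaction-modification modes:

``none``
    All ``mu = 1`` (plain trophic model).
``full``
    ``mu_ij`` evaluated from the live modifier densities (higher-order
    terms: each modified flow depends on three species).
``pairwise``
    Trophic terms with ``mu = 1`` plus, per TIM, the equivalent pairwise
    non-trophic terms obtained by freezing the trophic partner at its
    starting-equilibrium density: ``+ a_ij Bj* (1 - mu_ijk)`` on the
    resource and ``+ e_ij a_ij Bi* (mu_ijk - 1)`` on the consumer, with
    ``mu_ijk`` a function of the live modifier density only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import LinkParams, SpeciesParams, assign_body_masses, \
    assign_link_params, assign_species_params
from .tims import TIMSet, log10_modification_slope
from .webgen import FoodWeb, generate_niche_web, is_connected, trophic_levels

__all__ = [
    "IntegrationConfig",
    "CommunityState",
    "Community",
    "percapita_rates",
    "rates_and_jacobian",
    "integrate_to_steady_state",
    "build_initial_community",
    "CommunityGenerationError",
]

MODES = ("none", "full", "pairwise")


class CommunityGenerationError(RuntimeError):
    """Raised when no acceptable community is found within the attempt cap."""


@dataclass
class IntegrationConfig:
    """Numerical controls for steady-state integration.

    The system is integrated in windows of ``t_window`` model time
    units; it is declared converged when the largest relative biomass
    change across a window, over species above the extinction
    threshold, drops below ``rel_tol``. Runs exceeding ``t_max`` are
    flagged unconverged.
    """

    t_window: float = 500.0
    t_max: float = 100_000.0
    rel_tol: float = 1e-4
    solver_rtol: float = 1e-7
    solver_atol: float = 1e-11
    method: str = "LSODA"
    extinction_threshold: float = 1e-4
    #: cap on right-hand-side evaluations per steady-state run; runs
    #: exceeding it (pathologically stiff trajectories) count as failed
    max_nfev: int = 150_000


@dataclass
class CommunityState:
    """Biomass state: live densities plus the stored reference vector."""

    B: np.ndarray
    B_star: np.ndarray
    time: float = 0.0


@dataclass
class Community:
    """An equilibrated, pruned community ready for robustness tests.

    Species are re-indexed ``0 .. S-1`` over the persisting set;
    ``original_ids`` maps back to the indices of the generated web.
    ``B_star`` is the accepted starting-equilibrium density vector that
    anchors TIMs (``mu(Bk*) = 1``) and the pairwise partition.
    """

    web: FoodWeb
    species: SpeciesParams
    links: LinkParams
    B_star: np.ndarray
    original_ids: np.ndarray
    seed: int | None = None
    community_id: int = 0

    @property
    def S(self) -> int:
        return self.species.S

    def state(self) -> CommunityState:
        return CommunityState(B=self.B_star.copy(), B_star=self.B_star.copy())


def _link_mu(B: np.ndarray, links: LinkParams, tims: TIMSet | None,
             mode: str) -> np.ndarray:
    if mode == "full" and tims is not None and tims.n_tims:
        return 10.0 ** tims.link_log10_mu(B, links.n_links)
    return np.ones(links.n_links)


def percapita_rates(
    B: np.ndarray,
    species: SpeciesParams,
    links: LinkParams,
    tims: TIMSet | None = None,
    mode: str = "none",
    m: np.ndarray | None = None,
    B_star: np.ndarray | None = None,
) -> np.ndarray:
    """Per-capita growth rates ``(1/Bi) dBi/dt`` at biomass vector ``B``.

    ``mode`` selects how TIMs enter (see module docstring). ``m``
    overrides the external mortality stored in ``species``; pairwise
    mode requires ``B_star`` (reference densities for the frozen
    coefficients) and at most one TIM per link.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    Bc = np.maximum(np.asarray(B, dtype=float), 0.0)
    if m is None:
        m = species.m
    p = species.r - m - Bc / species.K

    res, con = links.resource, links.consumer
    mu = _link_mu(Bc, links, tims, mode)
    np.subtract.at(p, res, mu * links.a * Bc[con])
    np.add.at(p, con, links.e * mu * links.a * Bc[res])

    if mode == "pairwise" and tims is not None and tims.n_tims:
        if len(np.unique(tims.link_index)) != tims.n_tims:
            raise ValueError(
                "pairwise mode supports at most one modifier per trophic "
                "link (multiplicative multi-modifier combination cannot be "
                "partitioned into pairwise terms)"
            )
        if B_star is None:
            raise ValueError("pairwise mode requires B_star")
        mu_t = 10.0 ** tims.log10_mu(Bc)
        li = tims.link_index
        a, e = links.a[li], links.e[li]
        np.add.at(p, tims.resource, a * B_star[tims.consumer] * (1.0 - mu_t))
        np.add.at(p, tims.consumer, e * a * B_star[tims.resource] * (mu_t - 1.0))
    return p


def rates_and_jacobian(
    B: np.ndarray,
    species: SpeciesParams,
    links: LinkParams,
    tims: TIMSet | None,
    mode: str,
    m: np.ndarray | None,
    B_star: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """``dB/dt`` and its dense Jacobian (for stiff integration).

    ``dBi/dt = Bc_i p_i`` with ``Bc = max(B, 0)``;
    ``J = diag(p) * 1[B > 0] + diag(Bc) dp/dB``. The ``dp/dB`` TIM block
    uses ``d mu/dB_k = mu * s / B_k`` where ``s`` is the analytic slope
    of ``log10 mu`` against ``x = log10(Bk/Bk*)``.
    """
    S = species.S
    Bc = np.maximum(np.asarray(B, dtype=float), 0.0)
    if m is None:
        m = species.m
    p = species.r - m - Bc / species.K
    Jp = np.zeros((S, S))
    Jp[np.diag_indices(S)] = -1.0 / species.K

    res, con = links.resource, links.consumer
    mu = _link_mu(Bc, links, tims, mode)
    a, e = links.a, links.e
    np.subtract.at(p, res, mu * a * Bc[con])
    np.add.at(p, con, e * mu * a * Bc[res])
    np.subtract.at(Jp, (res, con), mu * a)
    np.add.at(Jp, (con, res), e * mu * a)

    if tims is not None and tims.n_tims and mode != "none":
        Bk = Bc[tims.modifier]
        slope = log10_modification_slope(
            Bk, tims.alpha, tims.tau, tims.sigma, tims.Bk_star
        )
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            dln_dBk = np.where(Bk > 0.0, slope / Bk, 0.0)
        li = tims.link_index
        if mode == "full":
            # d mu_link / dBk = mu_link * d ln mu_t / dBk
            dmu = mu[li] * dln_dBk
            np.subtract.at(Jp, (tims.resource, tims.modifier),
                           a[li] * Bc[tims.consumer] * dmu)
            np.add.at(Jp, (tims.consumer, tims.modifier),
                      e[li] * a[li] * Bc[tims.resource] * dmu)
        else:  # pairwise
            if B_star is None:
                raise ValueError("pairwise mode requires B_star")
            mu_t = 10.0 ** tims.log10_mu(Bc)
            dmu_t = mu_t * dln_dBk
            np.add.at(p, tims.resource,
                      a[li] * B_star[tims.consumer] * (1.0 - mu_t))
            np.add.at(p, tims.consumer,
                      e[li] * a[li] * B_star[tims.resource] * (mu_t - 1.0))
            np.subtract.at(Jp, (tims.resource, tims.modifier),
                           a[li] * B_star[tims.consumer] * dmu_t)
            np.add.at(Jp, (tims.consumer, tims.modifier),
                      e[li] * a[li] * B_star[tims.resource] * dmu_t)

    alive = (np.asarray(B) > 0.0).astype(float)
    dB = Bc * p
    # transient overflow (huge mu on exploding trajectories) is handled
    # by the solver rejecting the step; keep the warning stream clean
    with np.errstate(over="ignore", invalid="ignore"):
        J = np.diag(p * alive) + Bc[:, None] * Jp
    return dB, J


def integrate_to_steady_state(
    B0: np.ndarray,
    species: SpeciesParams,
    links: LinkParams,
    tims: TIMSet | None = None,
    mode: str = "none",
    m: np.ndarray | None = None,
    B_star: np.ndarray | None = None,
    config: IntegrationConfig | None = None,
) -> tuple[np.ndarray, bool, bool]:
    """Integrate until the windowed steady-state criterion is met.

    Returns ``(B_final, converged, failed)``. ``failed`` marks solver
    breakdown (step-size collapse or non-finite state); such runs are
    excluded from experiment summaries. ``converged=False`` with
    ``failed=False`` means ``t_max`` was exhausted first.
    """
    cfg = config or IntegrationConfig()
    if mode == "pairwise" and tims is not None and tims.n_tims:
        # trip the unsupported-configuration check before integrating
        percapita_rates(B0, species, links, tims, mode, m, B_star)

    nfev = 0

    class _EffortExceeded(Exception):
        pass

    def rhs(t, B):
        nonlocal nfev
        nfev += 1
        if nfev > cfg.max_nfev:
            raise _EffortExceeded
        p = percapita_rates(B, species, links, tims, mode, m, B_star)
        return np.maximum(B, 0.0) * p

    def jac(t, B):
        return rates_and_jacobian(B, species, links, tims, mode, m, B_star)[1]

    B = np.asarray(B0, dtype=float).copy()
    t = 0.0
    history: list[float] = []
    while t < cfg.t_max:
        try:
            sol = solve_ivp(
                rhs, (t, t + cfg.t_window), B, method=cfg.method, jac=jac,
                rtol=cfg.solver_rtol, atol=cfg.solver_atol,
                dense_output=False,
            )
        except _EffortExceeded:
            return B, False, True
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            return B, False, True
        B_new = np.maximum(sol.y[:, -1], 0.0)
        t = sol.t[-1]
        active = np.maximum(B_new, B) > cfg.extinction_threshold
        denom = np.maximum(B_new, cfg.extinction_threshold)
        change = np.abs(B_new - B) / denom
        B = B_new
        if not np.any(active) or np.max(change[active]) < cfg.rel_tol:
            return B, True, False
        # Bail early on runs that cannot plausibly make t_max: project
        # the geometric decay of the window change over an 8-window
        # baseline and require, with a 2x safety factor against
        # oscillation aliasing, that rel_tol is reachable in the
        # remaining horizon. True limit cycles (no decay) bail here.
        history.append(float(np.max(change[active])))
        if len(history) >= 9 and history[-1] > 10 * cfg.rel_tol:
            ratio = (history[-1] / history[-9]) ** 0.125
            if ratio >= 1.0:
                return B, False, False
            need = np.log(cfg.rel_tol / history[-1]) / np.log(ratio)
            if t + 2.0 * need * cfg.t_window > cfg.t_max:
                return B, False, False
    return B, False, False


@dataclass
class GenerationLog:
    """Accounting for the rejection-sampling community generator."""

    attempts: int = 0
    rejected_structure: int = 0
    rejected_unconverged: int = 0
    rejected_small: int = 0
    rejected_disconnected: int = 0


def _prune(web: FoodWeb, species: SpeciesParams, links: LinkParams,
           keep: np.ndarray) -> tuple[FoodWeb, SpeciesParams, LinkParams]:
    """Compact a community to the persisting species (re-indexed)."""
    old_ids = np.nonzero(keep)[0]
    new_of_old = -np.ones(web.S, dtype=np.int64)
    new_of_old[old_ids] = np.arange(len(old_ids))

    lk = keep[links.resource] & keep[links.consumer]
    new_links = LinkParams(
        resource=new_of_old[links.resource[lk]],
        consumer=new_of_old[links.consumer[lk]],
        a=links.a[lk], e=links.e[lk], omega=links.omega[lk],
    )
    new_web = FoodWeb(
        S=len(old_ids),
        consumers=new_links.consumer.copy(),
        resources=new_links.resource.copy(),
        niche_values=web.niche_values[old_ids],
        target_C=web.target_C,
        seed=web.seed,
    )
    new_species = SpeciesParams(
        M=species.M[old_ids], r=species.r[old_ids], K=species.K[old_ids],
        m=species.m[old_ids], level=species.level[old_ids],
    )
    return new_web, new_species, new_links


def build_initial_community(
    S: int = 35,
    C: float = 0.14,
    rng: np.random.Generator | int | None = None,
    retention_min: int = 18,
    B_init: float = 10.0,
    config: IntegrationConfig | None = None,
    max_attempts: int = 200,
    community_id: int = 0,
) -> tuple[Community, GenerationLog]:
    """Generate one retained starting community by rejection sampling.

    Draw a niche web, parameterize it, start every density at
    ``B_init`` and integrate to equilibrium (settling extinctions to
    exactly zero between integration rounds). The community is accepted
    iff at least ``retention_min`` species persist above the extinction
    threshold and the persisting subweb is connected; otherwise a fresh
    web is drawn. Structurally degenerate draws (disconnected webs,
    consumers with no chain to a producer) are rejected outright rather
    than patched.
    """
    cfg = config or IntegrationConfig()
    gen = np.random.default_rng(rng)
    log = GenerationLog()
    for _ in range(max_attempts):
        log.attempts += 1
        seed = int(gen.integers(2**31))
        web = generate_niche_web(S, C, seed)
        try:
            levels = trophic_levels(web)
        except ValueError:
            log.rejected_structure += 1
            continue
        if not is_connected(web) or not np.any(levels == 1):
            log.rejected_structure += 1
            continue
        sub = np.random.default_rng(seed)
        M = assign_body_masses(levels, sub)
        species = assign_species_params(M, levels, sub)
        links = assign_link_params(web, M, sub)

        B = np.full(S, float(B_init))
        ok = True
        for _round in range(12):
            B, converged, failed = integrate_to_steady_state(
                B, species, links, config=cfg)
            if failed or not converged:
                ok = False
                break
            dead = B < cfg.extinction_threshold
            if np.all(B[dead] == 0.0):
                break
            B[dead] = 0.0
        if not ok:
            log.rejected_unconverged += 1
            continue

        keep = B >= cfg.extinction_threshold
        if int(keep.sum()) < retention_min:
            log.rejected_small += 1
            continue
        pweb, pspecies, plinks = _prune(web, species, links, keep)
        if not is_connected(pweb):
            log.rejected_disconnected += 1
            continue
        community = Community(
            web=pweb, species=pspecies, links=plinks,
            B_star=B[keep].copy(), original_ids=np.nonzero(keep)[0],
            seed=seed, community_id=community_id,
        )
        return community, log
    raise CommunityGenerationError(
        f"no acceptable community in {max_attempts} attempts "
        f"(log: {log})"
    )
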