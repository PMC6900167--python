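# Methods

## The model

`timweb` simulates the robustness of model food webs in which the
strength of consumer–resource interactions can be modulated by third
species — *trophic interaction modifications* (TIMs) — and compares that
higher-order representation against the equivalent *pairwise*
non-trophic effects (NTEs).

Biomass densities follow a Lotka–Volterra system with a linear
(Holling type I) functional response and logistic self-regulation:

    dBi/dt = Bi ( ri − mi − Bi/Ki
                  − Σ_{j ∈ consumers of i} μij aij Bj
                  + Σ_{l ∈ resources of i} μli eli ali Bl )

Parameters derive from quarter-power body-mass scaling: producers have
r = 1 and K ~ U(1, 10); consumers have r = −0.1 M^(−1/4) and
K ~ 10^U(2,3) (weak self-regulation, well above typical densities);
attack rates are a_ij = ω_j M_j^(−1/4) with the generality weight
ω_j = 1/n fixed at assignment for a consumer with n resources, and
assimilation efficiencies e_ij ~ U(0.05, 0.15). External mortality m is
zero except for the targeted species during a robustness test (m = 1).

Topologies come from the niche model (35 species, connectance 0.14,
cannibalistic links removed). Communities start at B = 10 per species,
are integrated to equilibrium, species below 10⁻⁴ are settled to zero,
and the community is retained only if at least 18 species persist and
the persisting web is connected (undirected projection). The accepted
equilibrium densities B\* anchor everything downstream.

## Body masses

The level-dependent body-mass distribution is not fully pinned down by
the protocol we reproduce, so the package uses a standard allometric
default: log10 M ~ Normal(2·(level − 1), 0.5), i.e. a median
consumer–resource mass ratio of 100 per trophic level, with trophic
levels defined as 1 + the shortest chain length to a producer
(integer levels, matching the discrete level classes used for the rate
assignments). Both choices are exposed (`assign_body_masses`
arguments); every downstream quantitative statistic inherits this
reconstruction uncertainty.

## The modification function

A TIM (i, j, k) rescales the attack rate a_ij by μ_ijk(B_k), a
Gompertz sigmoid of the modifier's log-density divergence
x = log10(B_k / B_k\*), with three controls: maximum log-slope α
(facilitating > 0, interfering < 0), proportional-change threshold τ,
and total span σ. With g = e·α/σ and x_t = log10(1 + τ):

    log10 μ = σ·exp(−exp(−g·(x − x_t))) − σ·exp(−exp(−g·(0 − x_t)))

This closed form is a *reconstruction* built to satisfy the properties
that define the parameterization: μ(B_k\*) = 1 exactly (interaction
strengths at the starting equilibrium already include the modifier's
effect), sup μ / inf μ = 10^σ, and max |d log10 μ / dx| = |α|, attained
at the threshold. τ is read as a *linear* proportional change — the
threshold sits at B_k = (1 + τ)·B_k\*. We also evaluated a log-scale
reading (threshold at B_k = 10^τ·B_k\*); the linear reading reproduces
the published median attack-rate disruption statistic (~5.6-fold,
see below) to within a few percent, while the log reading
underestimates it by ~25%, so the linear form is the package default.
Degenerate draws α = 0 evaluate as μ ≡ 1 (the continuous limit);
B_k = 0 evaluates the finite asymptote, so a modifier's influence
persists at a finite level after its extinction. Multiple modifiers of
one link combine multiplicatively (synergistically): μ_ij = Π_k μ_ijk.

## Pairwise partition

Each TIM's flow term splits into a plain trophic term plus a
non-trophic remainder by freezing the trophic partner at B\*: the
resource receives the per-capita term a_ij·B_j\*·(1 − μ_ijk) and the
consumer e_ij·a_ij·B_i\*·(μ_ijk − 1), with μ_ijk still a live function
of B_k alone. Both representations agree exactly on the reference
manifold (B_i = B_i\*, B_j = B_j\*); away from it the pairwise terms
ignore the partner's density — in particular they survive the
partner's extinction. The partition requires at most one modifier per
link (the multiplicative combination is not additively separable), and
coefficients are frozen once at partition time and never updated.

## Experiments

A robustness test sets m = 1 on one targeted species, integrates to a
new steady state, and classifies every species against its own B\*:
extinct (< 10⁻⁴), functionally extinct (< B\*/10), exploded (> 10·B\*),
else persisting. The target is excluded from all secondary counts.

* **Comparison protocol (Test 1):** TIM rate 0.05 per (link, modifier)
  combination, α ~ U(−4, 4), σ ~ U(0.1, 4), τ ~ U(−1, 1), at most one
  modifier per interaction; every species of every community is
  targeted in turn under three modes (no-TIM, full, pairwise) with
  identical TIM draws.
* **Distribution protocol (Test 2):** rate 0.08, α ~ U(−3, 3),
  σ ~ U(0.1, 3), unlimited modifiers, full mode only; per-target TIM
  authorship (total / interfering / facilitating) feeds log-link
  Poisson regressions of secondary-extinction counts, reported as
  100·(exp(β) − 1) percent extra extinctions per additional TIM.

Post-hoc metrics use the *starting* (pruned, re-indexed) web: trophic
distances and mean path lengths are undirected shortest paths; with a
TIM set supplied, the path-length graph additionally contains
modifier↔resource and modifier↔consumer edges for every TIM (the
modifier touches both trophic participants; this is a documented
modelling choice, configurable by simply not passing the TIM set). The
expected-incoming-NTE baseline for a species with d trophic links is
d·(S − 2)·rate, split half/half between beneficial and detrimental
under the sign-symmetric α ranges (the split mass is an argument for
asymmetric ranges). The perturbation-response census reduces one
random species' density by 1%, evaluates all per-capita growth-rate
changes relative to the unperturbed state (which cancels the
integration residual), and pools the signs of responses with magnitude
above 10⁻¹⁰.

## Numerical choices

Integration uses LSODA with an analytic Jacobian (including the TIM
terms via the closed-form slope of log10 μ), solver tolerances
rtol = 10⁻⁷ / atol = 10⁻¹¹, in windows of 500 model-time units.
Convergence is declared when the largest relative biomass change
across a window, over species above the extinction threshold, falls
below rel_tol = 10⁻⁴ — orders of magnitude finer than the coarsest
classification boundary (a factor of 10). The horizon is
t_max = 10⁵; runs whose window-to-window change decays too slowly to
reach rel_tol within the horizon (projected geometrically over an
8-window baseline, with a 2× safety factor) are flagged unconverged
early, as are true limit cycles (no decay) and integrator breakdowns
(step failure, non-finite state, or more than 150,000 right-hand-side
evaluations — rare pathologically stiff TIM draws with σ ≈ 0.1 and
|α| ≈ 4). Unconverged and failed runs are recorded and excluded from
summary statistics. These criteria were calibrated against the plain
trophic model's slow post-perturbation transients; stricter per-window
tolerances (10⁻⁵–10⁻⁶) flag a large fraction of slowly-damping
oscillatory runs that do eventually settle, which biases suite means
by preferentially excluding TIM-heavy cascades.

Species are never hard-removed during integration: biomass is clamped
at zero only if the integrator steps negative (dead species then stay
exactly at zero since dB/dt = B·p). Classification happens once, at
the end. During community assembly, species below 10⁻⁴ are settled to
exactly zero between integration rounds until the persisting set is
stable.

## What the generator emulates — and what it does not

The synthetic communities emulate allometrically structured,
niche-model food webs with randomly placed modifications: every
potential (link, modifier) combination is equally likely. Real NTE
networks show non-random structure (e.g. consumer-avoidance TIMs link
trophically close species), saturating functional responses, and
antagonistic modifier combinations — none of which are modelled here.
Passing tests therefore demonstrate internal consistency of the
higher-order-versus-pairwise comparison under these idealized
conditions, not quantitative predictions for real communities.

## Reduced replication

The bundled test suite runs the comparison protocol on 10 communities
and the distribution protocol on 8; the acceptance script uses 14 and
11. At these sizes the qualitative signatures (robustness ordering,
distance shift, regression signs) are stable across seeds, while
per-test means retain visible Monte-Carlo and between-community
variance; the full-scale study behind the reproduction targets used
200 communities.

## Known limitations

* The body-mass distribution, the exact Gompertz algebra, and the
  convergence criteria are reconstructions; quantitative targets are
  matched in ordering and magnitude, not to printed precision.
* The unconverged-run fraction here (~10–25% in TIM-attached modes) is
  larger than the ~6% reported at full scale, and exclusions are not
  random: oscillatory runs carry heavier cascades on average.
* Integer (shortest-chain) trophic levels; no fractional prey-averaged
  levels.
* The pairwise mode is undefined for multi-modifier links by
  construction; the comparison protocol enforces the one-modifier cap.
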