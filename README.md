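# timweb

Dynamic food-web simulations that ask a precise question about
**higher-order interactions**: when a third species modulates the
strength of a consumer–resource interaction (a *trophic interaction
modification*, TIM), does representing that process faithfully — as a
three-species term — change community robustness, compared to the common
shortcut of recasting it as a pair of direct *non-trophic effects*
(NTEs) from the modifier onto each trophic participant?

The package is for theoretical ecologists and anyone studying dynamics
on networks with non-pairwise coupling. It provides:

* **Niche-model webs** (35 species, connectance 0.14 by default) with
  allometric Lotka–Volterra dynamics,
  `dBi/dt = Bi (ri − mi − Bi/Ki − Σj μij aij Bj + Σl μli eli ali Bl)`,
  parameterized by quarter-power body-mass scaling.
* **TIMs** via an anchored Gompertz sigmoid of the modifier's density:
  with `x = log10(Bk/Bk*)`, `g = e·α/σ` and threshold
  `x_t = log10(1+τ)`,
  `log10 μ = σ·exp(−exp(−g(x−x_t))) − σ·exp(−exp(−g(0−x_t)))`,
  so μ(Bk\*) = 1 exactly, log10 μ spans exactly σ, and the maximum
  log-slope is α (facilitating > 0, interfering < 0). Multiple
  modifiers combine multiplicatively.
* **The exact pairwise partition** of each TIM into two frozen-coefficient
  NTE terms (`aij·Bj*·(1−μ)` on the resource, `eij·aij·Bi*·(μ−1)` on the
  consumer), which matches the full model on the starting-equilibrium
  manifold and diverges from it away from equilibrium.
* **A robustness experiment engine**: targeted external mortality
  (m = 1), stiff integration to a new steady state (LSODA with analytic
  Jacobian), and per-species classification as persisting / extinct
  (< 10⁻⁴) / functionally extinct (< B\*/10) / exploded (> 10·B\*).
* **Post-hoc metrics**: trophic-distance distributions of casualties,
  expected and realized incoming-NTE counts, Poisson regressions of
  extinction counts on TIM authorship, path-length and attack-rate
  audits, and a perturbation-response sign census.

## Worked example

```python
from timweb import build_initial_community, run_robustness_test
from timweb.experiments import TEST1_TIM_CONFIG

community, log = build_initial_community(S=35, C=0.14, rng=11)
print(f"retained community: {community.S} species, "
      f"{community.links.n_links} trophic links "
      f"(after {log.attempts} candidate webs)")

tims = TEST1_TIM_CONFIG.sample(community, rng=7)
print(f"attached {tims.n_tims} TIMs "
      f"({int((tims.alpha > 0).sum())} facilitating, "
      f"{int((tims.alpha < 0).sum())} interfering)")

for mode in ("none", "full", "pairwise"):
    out = run_robustness_test(community, target=1, mode=mode,
                              tims=None if mode == "none" else tims)
    print(f"{mode:>8}: {out.n_extinct} secondary extinctions "
          f"(converged={out.converged})")
```

prints

```
retained community: 18 species, 30 trophic links (after 29 candidate webs)
attached 14 TIMs (4 facilitating, 10 interfering)
    none: 2 secondary extinctions (converged=True)
    full: 8 secondary extinctions (converged=True)
pairwise: 14 secondary extinctions (converged=True)
```

Read this as: a 35-species niche web equilibrated down to an
18-species persistent community; killing species 1 in the plain
trophic model drags two other species below the extinction threshold.
With 14 randomly placed interaction modifications the cascade grows to
eight — but when the *same* modifications are frozen into equivalent
pairwise effects, it nearly doubles again to fourteen. Higher-order
coupling is the more robust representation: modified flows scale with
the product of both trophic participants, so disruptions self-attenuate
as densities fall, whereas frozen pairwise effects persist even after
the mechanism carrying them is gone. Suite-level, the mean ordering
`none < full < pairwise` is strongly significant under paired tests;
single targets vary (and a minority of runs end in sustained
oscillations and are flagged unconverged and excluded, as above).

The same engine runs from the shell:

```bash
timweb test1 --seed 1 --out runs/test1     # three-mode comparison suite
timweb test2 --seed 2 --out runs/test2     # denser-TIM distribution suite
timweb metrics --results runs/test2 --out runs/metrics
timweb replay --community runs/test1/communities/0003 --target 5 --mode full
```

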