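# effdyn

Distribution dynamics of regional healthcare-system efficiency.

`effdyn` is for health economists and public-health analysts who want to
know not just *how efficient* each region's healthcare system is, but
whether regions **move** between efficiency tiers over time or lock into
persistent "efficiency clubs" — and whether those moves depend on what the
neighbouring regions are doing.  It implements the full chain:

1. **DEA scoring** — input-oriented radial efficiency per region-year:
   BCC under variable returns to scale (pure technical efficiency, PTE),
   CCR under constant returns (TE), and scale efficiency SE = TE/PTE:

       theta* = min { theta : Σ λ_j x_j ≤ theta x_o,  Σ λ_j y_j ≥ y_o,
                      λ ≥ 0,  (Σ λ_j = 1 under VRS) }

2. **State discretisation** — pooled PTE cut at the 33rd/67th percentiles
   into low/medium/high relative-efficiency states (quartiles as a
   robustness scheme).
3. **Markov analysis** — one-step transition matrix `P` with
   `p_ij = n_ij / n_i.`, its stationary distribution `π` solving
   `πP = π, Σπ = 1`, and persistence/mobility summaries, with
   region- and period-subset variants.
4. **Spatial Markov** — transition matrices estimated separately by
   neighbourhood context (tercile of the mean contemporaneous neighbour
   state), revealing spatially conditional dynamics.
5. **Transition equations** — linear-probability models of upward and
   downward mobility on resource-structure covariates, with two-way fixed
   effects and region-clustered (CR1) standard errors.

A seeded synthetic panel generator with a known production frontier, known
latent state dynamics, known spatial coupling and known covariate effects
provides ground truth for every stage; see `docs/methods.md` for the model
and its assumptions.

## Worked example

```python
import numpy as np
from effdyn import markov, spatial
from effdyn.reference import PUBLISHED_TRANSITION_MATRIX
from effdyn.states import StatePanel
from effdyn.synth import SyntheticConfig, generate_adjacency, generate_panel

# Long-run structure of the bundled published 3-state kernel
st = markov.stationary_of_matrix(PUBLISHED_TRANSITION_MATRIX)
print("pi =", np.round(st.pi, 4))
# pi = [0.4491 0.3085 0.2424]
```

Under that kernel the chain settles into a stratified long-run structure:
44.9% of the mass in the low-efficiency state, 30.8% medium, 24.2% high —
three coexisting clubs rather than convergence to a single tier.  The
mobility index `1 − trace(P)/3 = 0.1909` and the empty low→high cell
confirm strong persistence with no cross-tier leaps.

```python
# A spatially coupled synthetic panel, analysed end to end
cfg = SyntheticConfig(seed=7, spatial_coupling=0.5)   # 31 regions x 20 years
w = generate_adjacency(cfg)
_, truth = generate_panel(cfg, weights=w)
sp = StatePanel(truth.latent_states, np.full(2, np.nan), "truth")

ctx = spatial.assign_contexts(spatial.spatial_lag(sp, w))
for c, est in sorted(spatial.conditional_transitions(sp, ctx).items()):
    print(f"context {c}: p11 = {est.probabilities[0, 0]:.4f}  (n = {est.n_transitions})")
# context 1: p11 = 0.8730  (n = 109)
# context 2: p11 = 0.6176  (n = 225)
# context 3: p11 = 0.6182  (n = 255)
```

With spatial coupling switched on, a low-efficiency region surrounded by
low-efficiency neighbours stays low with probability 0.87, but only ~0.62
when its neighbourhood is more efficient — the conditional-dependence
signature the spatial Markov stage is designed to detect (and which
vanishes, as it should, when the generator's coupling is set to 0).

## Command line

```sh
effdyn simulate --seed 7 --out sim/            # synthetic panel + truth
effdyn dea sim/panel.csv --inputs x1,x2,x3 --outputs y1,y2 --out eff.csv
effdyn classify eff.csv --scheme tercile --out states.csv
effdyn markov states.csv --out markov
effdyn spatial-markov states.csv --weights sim/adjacency.csv
effdyn transitions states.csv sim/covariates.csv --outcome upward
effdyn run config.yaml                         # full pipeline from YAML
effdyn verify                                  # solver vs published values
```

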