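# matecomm

Stochastic (Gillespie/CTMC) birth–death simulation of microbial community
assembly, with and without mate limitation.

Microbial communities are typically more diverse than macro-organism
communities and carry many more rare taxa, while the size of the dominant
population looks the same at both scales. One trait cleanly separates the
two: microbes mostly reproduce asexually, so they never pay the
low-density cost of finding a mate. `matecomm` is a simulation toolkit for
quantifying that cost. It is aimed at theoretical/microbial ecologists who
want exact event-level stochastic simulations of neutral and
nearly-neutral community assembly, with mate-finding Allee effects as a
switchable mechanism.

## Model

A population of size N follows a continuous-time Markov chain with

* birth N → N+1 at rate `bN` (asexual), or `bN·(1 − e^{−2πR²VN/3})` when a
  mate must be encountered first (search radius R, speed V, random motion
  in three dimensions);
* death N → N−1 at rate `dN²` (logistic self-limitation; carrying
  capacity b/d).

Extinction is absorption at N = 0. A community couples one such chain per
member of a pool of potential colonists with an immigration reaction at
rate `(pool − S)·i` (S = current diversity) that resurrects an absent
taxon at size 2. The island-biogeography layer converts a mean time to
extinction (MTE) into an expected equilibrium diversity

    S* = pool · i / (1/MTE + i)

so anything that shortens persistence — like mate limitation — lowers
diversity, mostly by stripping out rare taxa.

## Worked example

```python
import numpy as np
from matecomm import (PopulationParams, SearchParams, estimate_mte,
                      mte_exact, expected_diversity, BiogeographyConfig)

asexual = PopulationParams(b=1.0, d=0.1)
poor    = PopulationParams(b=1.0, d=0.1, search=SearchParams(R=0.62, V=0.62))

for name, p in [("asexual", asexual), ("poor searcher", poor)]:
    mc = estimate_mte(p, n0=2, n_reps=1000, rng=np.random.default_rng(1))
    s_star = expected_diversity(BiogeographyConfig(i=0.001, pool_size=100,
                                                   mte=mte_exact(p, 2)))
    print(f"{name:14s} MTE {mc.mean:7.1f} ± {mc.se:5.1f}   "
          f"exact {mte_exact(p, 2):7.1f}   S* {s_star:5.1f}")
```

prints

```
asexual        MTE  2671.2 ±  89.2   exact  2737.3   S*  73.2
poor searcher  MTE   457.5 ±  15.5   exact   472.7   S*  32.1
```

Both populations would have the *same* deterministic carrying capacity
(≈10), yet the poor mate-searcher persists ~6× shorter because its birth
rate collapses at low density, and the island-biogeography layer converts
that into a drop from ~73 to ~32 coexisting taxa out of a pool of 100.
The Monte Carlo mean (`estimate_mte`) and the exact first-step linear
solve (`mte_exact`) are independent routes and agree within sampling
error. Explicit community simulation (`simulate_community`,
`run_community_experiment`) reproduces the same diversities from raw
birth/death/immigration events.

## Command line

```bash
matecomm mte --reps 1000 --seed 1 --outdir out/          # MTE per scenario
matecomm biogeo --seed 1 --outdir out/                   # analytic vs simulated diversity
matecomm community --seed 1 --outdir out/                # one community run
matecomm immigration-sweep --seed 1 --outdir out/
matecomm search-grid --seed 1 --outdir out/              # (R,V) grid vs asexual baseline
```

Each command writes tidy CSV (event logs as TSV) plus a JSON run manifest
recording the config snapshot, seed and output paths; reruns with the same
seed are byte-identical. Configs are flat YAML files (`--config`); all
quantities are in dimensionless model units.

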