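# Methods

## Model

`matecomm` simulates the assembly of a microbial community as a coupled set
of continuous-time Markov chains, one per potential colonist, advanced
exactly with the Gillespie direct method. A single population of size N
has two reactions:

* **birth** N → N+1 at rate `b·N` for asexual taxa. For sexually
  reproducing taxa the rate is multiplied by the probability that an
  individual encounters at least one mate,
  `P(N) = 1 − exp(−2πR²V·N/3)`, where individuals move randomly in three
  dimensions at speed `V` and detect mates within radius `R` (density is N
  per unit volume). `P` depends on (R, V) only through the product `V·R²`.
* **death** N → N−1 at rate `d·N²` (per-capita death rate `d·N`), the
  stochastic analogue of logistic self-limitation.

The deterministic skeleton `dN/dt = bN − dN²` has carrying capacity `b/d`;
mate limitation barely moves the high-density equilibrium (for the
parameter ranges used, `P(N) ≈ 1` for N ≳ 20) but sharply reduces the birth
rate when the population is small. That low-density suppression — a mate-
finding Allee effect — raises the probability that a small population's
next event is a death, and is the entire mechanism studied here: N = 0 is
absorbing, and the chain always reaches it eventually.

At the community level, each taxon runs its birth and death reactions
independently (no interspecific interactions), plus one aggregate
**immigration** reaction at rate `(pool_size − S)·i`, where S is current
diversity (count of taxa with N > 0) and `i` is the per-taxon immigration
constant. A firing selects one absent taxon uniformly at random and sets
it to the colonization size (default 2). Extinct taxa can recolonize with
their original parameters.

## Key parameters (dimensionless model units)

| parameter | default | meaning |
|---|---|---|
| `b` | 1.0 (or lognormal draws) | intrinsic per-capita birth rate |
| `d` | 0.1 | death constant; carrying capacity is `b/d` |
| `R`, `V` | none (asexual); studied range 0.55–1.2 | mate-search radius and speed |
| `i` | 0.001 | per-taxon immigration constant |
| `pool_size` | 100 | potential colonists |
| `colonize_size` | 2 | population size right after an immigration |
| `lognormal_mu`, `lognormal_sigma` | 0, 0.25 | heterogeneous growth-rate distribution (natural-log scale) |
| burn-in / interval / samples | 10⁷ / 2×10⁵ / 100 events | community sampling schedule |

The reference mate-search scenarios are *poor searcher* (R = V = 0.62),
*effective searcher* (R = V = 0.8) and *asexual* (no search term); all
three have nearly identical deterministic carrying capacities at b = 1,
d = 0.1, so differences in persistence are purely stochastic, low-density
effects. The single-population death constant uses the same d = 0.1 as the
community experiments, consistent with the rate curves crossing at N = 10.

## Mean time to extinction

`estimate_mte` averages absorption times over independent replicates
(censored runs — none at the defaults, horizon 10⁶ time units — are
counted, excluded from the mean and warned about). Independently,
`mte_exact` solves the first-step tridiagonal linear system for the
expected absorption time of the truncated chain (truncation `10·b/d + 50`,
birth disabled at the top state; results are verified stable to <0.1%
under truncation doubling via `scipy.linalg.solve_banded`). The Monte
Carlo estimator is required by the test suite to agree with the exact
oracle within three standard errors across parameter sets; at b = 1.0,
d = 0.1, N₀ = 2 the exact values are 2737 (asexual), 1577 (effective) and
473 (poor), and extinction-time SDs are of the same order as the means
(near-exponential absorption tail).

## Island-biogeography layer

Treating the S resident taxa as independent, the community loses taxa at
rate `S/MTE` and gains them at `(pool − S)·i`; equating the two gives the
equilibrium diversity `S* = pool·i/(1/MTE + i)`. The MTE entering the
formula is measured from the colonization size (2), because that is the
state in which immigration creates populations. Multiplying both rates by
a common constant (a change of time scale) moves the rate axes but not the
crossing point. `validate_against_simulation` compares `S*` against the
long-run mean of sampled diversity in the explicit coupled simulation.

Two numerical facts matter when interpreting that comparison. First, the
renewal argument is exact for the *time-weighted* mean diversity of
identical independent taxa: measured time averages match
`pool·MTE/(MTE + 1/i)` to within ~0.02 taxa. Second, the sampling protocol
is event-count based (snapshots every 2×10⁵ events), which over-samples
high-activity — hence high-diversity — excursions and sits ~0.5–0.9 taxa
above the time average. The package keeps the event-count protocol because
it is the study design being reproduced; the analytic-vs-simulated gap of
≲1 taxon should be read with that bias in mind. Successive snapshots are
also strongly autocorrelated (the diversity relaxation time `1/(i+1/MTE)`
≈ 300–700 time units spans several sampling intervals), so a single
100-sample run pins its own long-run mean only to about ±1 taxon; the
validation experiments therefore average 4 replicate runs of 200 samples
each, bringing the sampling error well below the one-taxon scale.

## Emergent-property summaries

Per-sample statistics are computed over extant taxa only (zeros mean
absent, and including them would dominate every moment): richness,
dominance (largest population), mean abundance, mean intrinsic growth rate
of extant taxa, and the moment-based sample skewness `g1 = m₃/m₂^{3/2}`
(no small-sample bias correction; shift- and scale-invariant). Turnover is
Bray–Curtis dissimilarity `Σ|x−y| / Σ(x+y)` between consecutive samples;
the community extinction rate is the reciprocal mean gap between
successive taxon-extinction events after burn-in. Undefined cases (empty
community, fewer than 3 taxa for skewness, <2 extinctions) are NaN/`NA`,
never silently dropped into aggregates as zeros.

## Experiment designs

* **Identical vs heterogeneous pools.** Heterogeneous pools draw `b` from
  lognormal(0, 0.25); the matched neutral control sets every taxon's `b`
  to the mean of those draws (or an explicit common value). Communities
  start empty and assemble through immigration.
* **Immigration sweeps** rerun both modes over a grid of `i` with
  replicate communities per point.
* **Search grid.** Heterogeneous communities across a grid of (R, V), each
  cell scaled by an asexual baseline. Cells and baseline share the same
  growth-rate draws and the same simulation seeds per replicate (common
  random numbers), which makes the scaled ratios exact 1 when mate
  limitation vanishes and sharply reduces their variance otherwise.

## Numerical and implementation choices

* Exact direct-method SSA throughout; no tau-leaping. Waiting times use
  `−log(1−u)/total`; each event consumes exactly two uniforms (the
  immigration branch reuses the rescaled selection uniform to pick the
  colonist, so no third draw is needed). Runs are bit-reproducible from a
  seed; the hot loops are numba-compiled and keep per-taxon rates plus an
  incrementally maintained total, resynchronized every 2²⁰ events to
  cancel float drift.
* Event logs keep immigration and extinction records always; per-event
  birth/death records are opt-in (`record_events=True`), since full logs
  at 3×10⁷ events per run are ~0.5 GB and only the rare-event records feed
  downstream statistics.
* `deterministic_equilibrium` returns the largest positive root of
  `b·P(N) = d·N` (with strong limitation a lower, unstable Allee threshold
  can also exist); bracketed Brent root-finding to relative tolerance
  1e−10, `None` when no positive root exists.
* Problem sizes in the shipped tests and reproduction script: 500–1000
  Monte Carlo extinction replicates, 4×200-sample identical-taxa community
  runs per scenario, and 10 replicate heterogeneous communities per
  condition at the full 10⁷-event burn-in — sized so Monte Carlo error is
  small against each quantity checked.

## What the simulations do and do not show

The generator *is* the model under study — there is no external data — so
tests demonstrate internal consistency (simulation vs exact chain algebra
vs analytic equilibrium) and reproduction of the study conditions, not
realism of any particular microbial system. Known limitations: no
interspecific interactions (competition, cross-feeding), no dormancy, a
well-mixed habitat with no spatial structure beyond the encounter kernel,
immigration independent of donor-pool dynamics, and a 1:1 sex ratio with
the total count N entering the encounter term. One reproduction gap is
documented: with the estimator above, the abundance skewness of the most
mate-limited heterogeneous communities stabilizes near 0.20, below the
published 0.269, although its qualitative behaviour (lower than the
asexual 0.51–0.57) is robust; no estimator variant consistent with the
other reproduced quantities closes that gap. Optional figure generation is
out of scope: all outputs are tidy CSV/TSV suitable for any plotting tool.
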