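# islandiicr

Demographic inference under piecewise-stationary symmetric island models,
driven by the IICR (Inverse Instantaneous Coalescence Rate).

## The problem

A PSMC plot from a single diploid genome is routinely read as a history of
population-size changes.  Under population structure this reading is wrong:
the curve estimated by PSMC is the IICR,

```
IICR(t) = P(T2 > t) / f_T2(t),
```

the ratio of the survival and density of the coalescence time `T2` of two
lineages, which coincides with the size function `λ(t)` only under panmixia.
Under structure the same humps can be produced with *constant* population
size by changes in connectivity.  `islandiicr` takes the opposite view: it
fits an observed IICR with the exact IICR of a symmetric n-island model in
which the total migration rate `M` received by each island is constant
within time components and jumps at `γ` event times.  The inferred
parameters are

* `n` — the number of islands,
* `t_1 < … < t_γ` — event times (units of `2N` generations, or generations
  for scaled fits),
* `M_0 … M_γ` — per-component migration rates,
* `N` — the reference deme size (scaled fits only).

For two sampled lineages the island model lumps into a three-state Markov
chain (same deme / different demes / coalesced) whose generator per
component is

```
        S            D           C
S  [ -(1/s + M)      M          1/s ]
D  [  M/(n-1)     -M/(n-1)       0  ]
C  [     0            0          0  ]
```

and the exact IICR of a piecewise history follows by propagating the state
distribution through the components with matrix exponentials.  The fit
minimizes a weighted L1 distance between the target curve and the model
curve, with weights proportional to a power `ω` of the coalescence-time
density implied by the target (recent, coalescence-rich epochs count more;
`ω < 1` shifts weight toward the ancient past).  The search runs
differential evolution in rounds with elitist carry-over and a targeted
repair step for component misassignment.

Intended users: population geneticists who have a PSMC (or any stepwise
IICR estimate, or simulated `T2` samples) and want to ask what history of
*connectivity*, rather than of size, explains it.

## Worked example

```python
import numpy as np
from islandiicr import (
    Bounds, IICRInference, IslandDemography, exact_iicr, log_grid,
)

truth = IslandDemography(n=10, event_times=(1.5,), migration_rates=(5.0, 0.7))
target = exact_iicr(truth, log_grid(1e-2, 2e2, 64))

est = IICRInference(
    n_components=2,
    bounds=Bounds.uniform(1, n=(2, 50), t=(0.05, 100.0), M=(0.05, 100.0)),
    random_state=1,
)
est.fit(target)
print(est.demography_)
print(f"distance {est.distance_:.2e} after {est.rounds_} rounds")
```

prints

```
IslandDemography(n=10, event_times=(1.5,),
                 migration_rates=(4.999999999999999, 0.7000000000000003),
                 deme_sizes=(1.0, 1.0))
distance 1.60e-16 after 2 rounds
```

i.e. the ten islands, the event at `t = 1.5` (in `2N` generations) and both
migration rates are recovered to machine precision from the curve alone,
with the achieved distance far below the `1e-10` convergence tolerance.

Fitting a real PSMC file instead:

```
islandiicr infer --target french.psmc --components 5 --omega 0.2 \
    --scaled --mu 1.25e-8 --gen-time 25 --seed 7 --out french_c5.json
```

which also writes the inferred connectivity graph (the step function
`t ↦ M(t)`) as a TSV next to the result.  `islandiicr validate` runs
simulation-validation batches (scenario sampling → target → inference →
per-parameter nRMSD scoring).

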