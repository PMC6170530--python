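# coupcoord

Coupling coordination degree (CCD) assessment of two-system indicator
hierarchies, built for soil–vegetation co-development scoring in
ecological restoration (e.g. reclaimed opencast coal-mine dumps), but
applicable to any two coupled systems described by a plot × indicator
table.

## Who it is for

Restoration ecologists and land-reclamation assessors who have, per
plot, a set of vegetation indicators (canopy density, DBH, biomass, …)
and soil indicators (pH, bulk density, SOM, N/P/K, …) and want a
defensible answer to: *how well developed is each system, which one is
the "short plank", and how coordinated is their co-evolution?*

## The model

For plot *i* with min–max normalized indicator values
*x′<sub>ij</sub>* ∈ [0, 1]:

1. **Weights.** Each indicator gets an objective entropy weight within
   its subsystem: with *P<sub>ij</sub> = x′<sub>ij</sub> / Σ<sub>i</sub>
   x′<sub>ij</sub>*,

   *e<sub>j</sub> = −(1/ln m) Σ<sub>i</sub> P<sub>ij</sub> ln P<sub>ij</sub>*,  *w<sub>j</sub> = (1 − e<sub>j</sub>) / Σ<sub>j</sub>(1 − e<sub>j</sub>)* ,

   and each subsystem gets a subjective AHP weight within its system
   (principal eigenvector of a reciprocal pairwise comparison matrix,
   checked with Saaty's consistency ratio CR = CI/RI ≤ 0.1). The
   combined indicator weight is the product of the two layers and sums
   to 1 within each system.

2. **System scores.** *V<sub>i</sub> = Σ<sub>j∈veg</sub> w<sub>j</sub>
   x′<sub>ij</sub>* and *S<sub>i</sub> = Σ<sub>j∈soil</sub>
   w<sub>j</sub> x′<sub>ij</sub>*, both in [0, 1].

3. **Coupling.** *C = √(V·S) / (V + S)* ∈ [0, 0.5], maximal exactly
   when *V = S* > 0.

4. **Coordination.** *D = √(C·T)* with *T = αV + βS* (default
   α = β = 0.5, i.e. *D = (V·S)<sup>1/4</sup>/√2*), banded into
   low/primary/intermediate/well/high coordination; the lag ratio
   *V/S* diagnoses the lagging system (≤ 0.8 vegetation lagging,
   0.8–1.2 synchronous, > 1.2 soil lagging).

A radical-free variant *D = C·T* is available (`--literal-eq38` /
`literal_d=True`) for comparison studies.

## Worked example

The shipped fixture encodes a published five-plot evaluation of
reclaimed mine-dump plots on the Loess Plateau (four reclamation
patterns and one undisturbed original landform) against an
18-indicator hierarchy. The raw field table was never released, so a
synthetic matrix is calibrated to the published per-plot (V, S) scores
and pushed through the full pipeline:

```python
from coupcoord import generate_matrix, run_pipeline, scenario_from_scores
from coupcoord.datasets import (
    PINGSHUO_SYSTEM_SCORES, pingshuo_ahp_config, pingshuo_index,
)

index = pingshuo_index()
V = {p: vs[0] for p, vs in PINGSHUO_SYSTEM_SCORES.items()}
S = {p: vs[1] for p, vs in PINGSHUO_SYSTEM_SCORES.items()}
raw = generate_matrix(scenario_from_scores(V, S, index))
report = run_pipeline(raw, index, pingshuo_ahp_config())
print(report.summary_frame().to_string(index=False))
```

prints (anchor rows omitted; see `examples/01_mine_reclamation_evaluation.py`):

```
plot  vegetation_score  soil_score  ratio      C    D        coordination_class                 lag_class
 RUA              0.32        0.25   1.28 0.4962 0.38      primary coordination       soil lagging behind
  RP              0.57        0.74   0.77 0.4958 0.57 intermediate coordination vegetation lagging behind
  RM              0.16        0.35   0.46 0.4640 0.34      primary coordination vegetation lagging behind
  PM              0.41        0.46   0.89 0.4992 0.47 intermediate coordination   synchronous development
  OP              0.50        0.21   2.38 0.4564 0.40      primary coordination       soil lagging behind
```

Reading RP (a broadleaf–conifer mixture): soil (0.74) outpaces
vegetation (0.57), so vegetation is the short plank (ratio 0.77); the
two systems interact strongly (C = 0.4958, near the 0.5 ceiling) and
the plot reaches intermediate coordination (D = 0.57), the best of the
five. RM (a legume monoculture) has the weakest vegetation (0.16) and
only primary coordination.

Other entry points: `examples/02_custom_index_from_csv.py` (your own
CSV + hierarchy), `examples/03_ahp_consistency.py` (judgment matrices
and CR), `examples/04_synthetic_scenarios.py` (ground-truth
generation), and the `coupcoord run|synth|validate` command line.

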