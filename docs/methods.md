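# Methods

## Scope and data model

`coupcoord` evaluates a two-level indicator hierarchy (systems →
subsystems → indicators) against a plot × indicator table of raw
measurements. The engine accepts any such hierarchy with exactly two
systems at the coupling step; the shipped fixture is the 18-indicator
soil–vegetation system used for reclaimed opencast-mine plots (2
systems, 5 subsystems). Column order everywhere is a pure function of
the index-system definition, never of file layout, so results are
invariant to column permutation in input CSVs.

## Normalization

Min–max standardization per indicator column over plots:
`x' = (x − min)/(max − min)` for benefit indicators, reflected for
cost indicators. Degenerate (constant) columns are mapped to all
zeros with a warning rather than raising: a constant column carries
no ranking information, and the zero column then receives maximal
entropy and hence zero weight downstream, which is the behaviour a
surveyor wants when one assay saturates. Float round-off is clipped
back into [0, 1].

The shipped mine fixture declares *all* 18 indicators benefit-typed,
including pH and bulk density, which soil-science convention would
reverse-code. This is deliberate: the published scores that the
fixture reproduces were computed with uniform benefit orientation,
and the raw supplementary data that would let one recompute under
reverse coding was never released. Users applying the package to
their own surveys should set `direction: cost` for such indicators.

## Weighting

**Entropy layer (objective).** Within each subsystem, indicator
weights follow 1 − e_j where e_j is the Shannon entropy of the
column's share distribution across plots, normalized by ln m. The
convention 0·ln 0 = 0 is applied directly — min–max output
necessarily contains zeros — instead of epsilon-shifting the data,
which would distort weights by an arbitrary amount depending on the
epsilon. Entropy is undefined for a single plot (ln 1 = 0), so m ≥ 2
is enforced. A column summing to zero gets e = 1 and weight 0; a
subsystem whose columns are all uninformative falls back to equal
weights with a warning, keeping the pipeline total.

**AHP layer (subjective).** Subsystem weights within each system come
from a positive reciprocal pairwise comparison matrix via its
principal right eigenvector, computed by power iteration (tolerance
1e−12 on the weight vector, max 10 000 iterations — consistent
matrices converge in one step, 1–9-scale judgments within tens).
λ_max is estimated as the Rayleigh-style ratio at the converged
vector. Consistency uses CI = (λ_max − k)/(k − 1) and Saaty's RI
table up to k = 10; CR > 0.1 warns by default and raises under
`cr_strict`. The geometric-mean (log least squares) method is
provided as a cross-check; on consistent matrices the two agree to
numerical precision. Because practitioners often publish final
weights without their judgment matrices, direct subsystem weights are
accepted alongside pairwise form and are renormalized to sum 1.

The shipped `pingshuo_ahp.yaml` uses direct weights back-derived from
the published combined-weight table by summing each subsystem's block
(the entropy layer sums to 1 within a subsystem, so the block sum *is*
the subsystem weight): tree 0.6739 / herb 0.2255 / litter 0.1007;
basic 0.2000 / nutrient 0.8001.

**Combination.** combined(j) = subsystem_weight × entropy_weight, with
no renormalization: the product construction already sums to 1 within
each system, which is the scope the comprehensive scores need.

## Coupling coordination model

With per-plot scores V (vegetation) and S (soil), both weighted sums
in [0, 1]:

* C = √V·√S / (V + S), in [0, 0.5], symmetric, maximal iff V = S > 0.
  The factored square roots avoid underflow of V·S for very small
  scores. V + S = 0 defines C = 0 and flags the plot degenerate.
* T = αV + βS with α, β ≥ 0, α + β = 1 (default 0.5/0.5: the two
  systems are taken as equally important contributors).
* D = √(C·T), in [0, 1]. With α = β = 0.5 this reduces to the closed
  form D = (V·S)^¼ / √2, which the tests assert against the staged
  computation at 1e−12. Note the C ≤ 0.5 ceiling caps D at
  √0.5 ≈ 0.707 under equal coefficients, so the "high coordination"
  band above 0.8 is unreachable in this two-system form; it is kept
  for scheme compatibility.

The formulation D = C·T without the radical appears in parts of the
CCD literature; it compresses the scale quadratically and does not
reproduce the published plot results, so it is exposed only behind
`literal_d` / `--literal-eq38` for comparison studies.

## Classification

D bands: (0, 0.2] low, (0.2, 0.4] primary, (0.4, 0.6] intermediate,
(0.6, 0.8] well, (0.8, 1] high coordination. Lag-ratio bands:
(0, 0.8] vegetation lagging, (0.8, 1.2] synchronous, (1.2, ∞) soil
lagging. Intervals are half-open on the left (a boundary value
belongs to the lower band); D = 0 or ratio = 0 is folded into the
first band. When S = 0 the ratio is undefined: the plot classifies as
extreme soil lag if V > 0, degenerate otherwise. Both schemes are
overridable via YAML; the label of the topmost D band is itself a
configuration choice, as usage in the literature varies.

**Classification precision.** By default the pipeline bands D and V/S
after rounding to 2 decimals — the precision at which such tables are
printed and read. This matters exactly at knife edges: the original
landform plot in the shipped fixture computes D ≈ 0.4025, which reads
as 0.40 → primary coordination in the published table but would band
as intermediate at full precision. `classification_precision=None`
(CLI `--full-precision-classes`) switches to banding the unrounded
values. Stored scores are always full precision; rounding (C to 4
decimals, D/V/S/ratio to 2) otherwise happens only in the summary
table.

## Synthetic data generator

The generator emulates the *tabular structure* of a reclamation
survey — a small plot × indicator matrix with per-indicator raw
ranges — not its ecology: no correlations among SOM/TN/etc., no
spatial structure, no measurement-error model beyond optional
Gaussian jitter. Passing tests therefore demonstrate the arithmetic
of the pipeline, not robustness to real survey noise.

Ground truth is injected on the normalized scale and inverted
affinely into raw ranges (`raw = low + x'·(high − low)`, reflected
for cost columns). Each target column must contain an exact 0 and 1
so the min–max inversion round-trips bitwise; otherwise generation
errors out rather than silently shifting the targets.
`scenario_from_scores` realizes arbitrary per-plot (V, S) by setting
every vegetation column of a plot to V and every soil column to S —
constant rows make the weighted score equal the constant for *any*
weight set summing to 1 per system — and appends all-0/all-1 anchor
plots when needed to pin column extrema. Anchor plots participate in
normalization and entropy weighting (harmlessly: they only widen
column ranges to the unit interval) and should be dropped from
downstream readings; the anchor ids are exported as constants.
Randomized generation threads a single integer-seeded
`numpy.random.Generator`; no global RNG state is touched.

## Shipped fixture and reproduction scale

The five-plot mine study is shipped as: the index hierarchy
(`pingshuo_index.yaml`), direct subsystem weights
(`pingshuo_ahp.yaml`), the published per-plot (V, S) scores, combined
indicator weights and coupling results (`coupcoord.datasets`). The
published 4-decimal C values for two plots differ in the 3rd–4th
decimal from what the 2-decimal printed (V, S) inputs give (the
authors evidently used unrounded scores), and one plot's printed
D = 0.46 recomputes as 0.466 from rounded inputs; the tests and the
acceptance script check exactly the subset of printed values that is
reachable from the printed inputs and treat the rest as documented
input-rounding slack. All computations are desk-scale: the full test
suite and the acceptance script each run in seconds (5 plots × 18
indicators; property checks use 10⁴ random score pairs and
judgment matrices up to order 7).

## Known limitations

* Exactly two systems at the coupling step; no three-system CCD
  generalizations, no temporal trajectories of D.
* No missing-data imputation: matrices must be complete and finite.
* No group-AHP aggregation or fuzzy AHP; one judgment matrix (or
  direct weight vector) per system.
* Entropy weighting is scale-free but range-sensitive: it operates on
  min–max output, so a single outlier plot compresses everyone else's
  shares.
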