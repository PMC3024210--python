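# Methods

## Model and procedure

The scan model is the standard circular Poisson scan: areas are
independent Poisson counts with mean proportional to population under the
null; a candidate zone is a circular window — a center area plus its
k nearest areas by centroid distance — and its evidence is the
log-likelihood ratio LLR(z), nonzero only for zones with a case excess
(inside relative risk I(z) = c_z/μ_z > 1). Windows grow per center until
their population would exceed `max_pop_fraction · N` (default 0.5, the
conventional cap, exposed everywhere as a flag). The MLC is the
LLR-maximizing window; its p-value comes from B multinomial null
replicates (p_i = n_i/N) via the positive-biased estimator
p = (1 + #{LLR* ≥ LLR_obs}) / (1 + B), which is exactly calibrated under
the null: with B = 199, p ≤ 0.05 occurs with probability 10/200 = 0.05.

The intensity procedure replicates the *observed* map instead of the
null: m multinomial draws with probabilities c_i/C (raw mean model) or
n_iθ̂_i / Σ n_jθ̂_j (smoothed model, θ̂ from local empirical-Bayes
smoothing). Each replicate's primary MLC only is recorded. The m maximal
LLRs are sorted ascending into f(j); an area's quantile q(a_i) is the
rank of the largest f value among replicate MLCs containing it, divided
by m, and 0 if it is in none. Because f is nondecreasing, this argmax is
the *highest* qualifying rank; ties in f are resolved to the highest rank,
which keeps q well defined when several replicates share an LLR value.
Replicates whose scan finds no excess (max LLR = 0) still occupy a rank
with f(j) = 0 but contribute no membership, so f stays defined on all of
{1..m} without letting "empty" replicates mark areas.

Smoothing follows the method-of-moments shrinkage
θ̂_i = w_i t_i + (1 − w_i) m_i with w_i = Ã/(Ã + m̃/n_i),
m̃ = Σy/Σn, s² = Σ n_i (t_i − m̃)²/Σ n_i, n̄ = Σn/K and
Ã = max(0, s² − m̃/n̄). The local variant evaluates these formulas on
each area's first-order neighbourhood.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `max_pop_fraction` | 0.5 | cap on window population as a fraction of N; conventional circular-scan maximum |
| `m` (`--reps`) | 999 | intensity replicates; the map sharpens gradually with m and runs can be stopped/resumed via checkpoints |
| `B` (`--null-reps`) | 999 | null replicates for the p-value; minimum attainable p is 1/(B+1) |
| shading levels | 0.90, 0.95, 0.99, 1.0 | quantile breakpoints for the map classes; class 0 (blank) is reserved for q = 0; per-map hand-tuning is expected and supported |
| `include_self` (local smoothing) | True | the neighbourhood is {i} ∪ neighbours(i); including the area itself is the common convention and keeps the estimate defined for isolated areas (which then retain their raw rate) |
| checkpoint interval | 50 replicates | granularity of resumable state |

## Synthetic benchmark

The generator emulates a rectangular hexagonal-lattice study map of 203
cells — laid out as 7 rows × 29 columns, since 203 factors exactly and
needs no deleted cells — with population 1000 per cell and centroids
jittered uniformly by ±0.05 of the cell spacing per axis so that no two
inter-centroid distances tie (window ordering is then unambiguous;
adjacency is taken from the clean lattice). Cases are drawn multinomially
with cell weights n_i inflated by a relative-risk factor inside the
injected cluster, so the "true" cluster appears only as a stochastic
excess in a noisy map.

Scenario defaults, chosen once as a realistic contrast and exposed as
parameters: circular clusters are 7-cell hex discs (a cell plus its
ring); the L-shape is an 11-cell corner (7-cell horizontal arm, 5-cell
vertical arm sharing the corner); relative risks are 8 ("very high"),
3 ("moderately high"), and (8, 5) / (3, 2) for the two components of the
high/moderate double clusters; the expected case total is 406 (2 per cell
on average). At risk 8 a 7-cell cluster holds ≈ 22% of all cases
(≈ 13 per cell against ≈ 1.5 outside) and is sharply detectable; at risk
3 it holds ≈ 10% and sits near the edge of detectability, which is the
qualitative contrast the two single-circle scenarios are meant to probe.

What the generator does **not** emulate: heterogeneous populations,
irregular area geometry and sizes, spatial covariates and autocorrelated
background risk. Passing the benchmark therefore shows that the
machinery recovers planted structure under idealized conditions; it does
not certify performance on real maps with strong population gradients.

## Numerical choices

- 0·log(0) ≡ 0 in the LLR when a zone holds all C cases; a zone covering
  the whole map has I(z) = 1 and scores 0.
- The scan hot path precomputes, per map, the per-center distance
  ordering and cumulative populations, and per case-total C the window
  expectations and a k·log k table; each replicate scan is then a gather,
  a cumulative sum and table lookups. The table path agrees with direct
  evaluation to ~1e-13 and the scalar formula is kept as the reference
  implementation.
- LLR ties between zones are broken by smaller population, then fewer
  members, then lowest center index; exact centroid-distance ties are
  broken by area index with a logged warning (the jittered generator never
  produces them).
- The replicate LLR sort is stable (ties keep replicate order).
- A negative moment estimate of the prior variance is clamped to 0,
  giving complete shrinkage to the (local) mean.
- Reproducibility: replicate r uses the r-th child of
  `SeedSequence(seed)`, so results are independent of batch size and a
  checkpoint-resumed run is bit-identical to a straight-through run.
- Degenerate inputs: all-zero replication probabilities, zero total
  cases, zero-population areas and asymmetric adjacency are rejected with
  named errors; proportional case maps return a flagged "no excess"
  result instead of an arbitrary zero-LLR zone.

## Design notes

- Zero-case areas keep probability 0 under the raw mean model — faithful
  to the stated multinomial. They can still earn q > 0 by falling inside
  a replicate MLC window, and the smoothed model exists precisely to give
  them positive replication probability from their neighbourhood.
- Adjacency for user maps can come from an edge list or, as a fallback,
  from a Delaunay triangulation of the centroids; both are offered because
  contiguity files are often missing for published maps.
- Only the primary MLC per replicate feeds the intensity function;
  secondary-cluster bookkeeping is deliberately out of scope.
- Coordinates are treated as planar; no projection support.

## Problem sizes used in the shipped checks

The test suite exercises the scan oracle on 200 random maps with K ≤ 12,
null calibration on 500 simulated 203-cell maps at B = 199, cluster
recovery on 50 runs of m = 199 for the single-circle and L scenarios,
30 runs of m = 999 for the double cluster, and 30 paired runs of m = 99
for the raw/smoothed contrast. `scripts/acceptance.py` recomputes the
same quantities at 15–25 runs per scenario and 200 null maps. These sizes
keep the full recomputation in the minutes range on a single CPU while
leaving the Monte Carlo assertions statistically comfortable.

## Known limitations

- Only circular windows; elliptic or irregular scan windows are not
  implemented (irregular shapes are *delineated* by the intensity map,
  not scanned directly).
- No space–time scan, no secondary-cluster reporting, no significance
  adjustment across areas for the q map (q is a descriptive plausibility
  measure, not a family-wise-corrected inference).
- The multinomial replication conditions on the observed total C; maps
  with very small C give coarse q lattices (multiples of 1/m) and wide
  intensity bounds, which is the intended behaviour, not an artifact.
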