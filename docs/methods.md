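# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `antplant`, and what the synthetic-data tests do and do not
demonstrate about real census data.

## Networks and metrics

A census table (one row per surveyed tree) is aggregated per elevation into
a quantitative bipartite network: rows are plant species, columns ant
species, cell `a_ij` the number of plant individuals of species *i*
occupied by ant species *j*. Construction drops unoccupied trees and — by
default — trees whose resident ant could not be identified ("uncertain"):
they have no species identity, though they still count as occupied for
occupancy rates. Both behaviours are flag-controlled. All-zero rows and
columns are pruned and labels sorted lexicographically, so networks are
deterministic functions of the census; metrics are defined only on pruned
matrices. An elevation with no usable record yields a typed empty network,
and every metric of an empty or degenerate network is NaN. NaNs propagate
into downstream statistics and are dropped pairwise (with the used `n`
reported), never silently replaced by zero.

* **Connectance** — binary: positive cells / (rows × columns).
* **Generality / vulnerability** — weighted effective partner counts.
  For ant species *j* with column total `d_j`, the effective number of
  plant partners is `exp(H_j)` with `H_j` the Shannon entropy of
  `a_ij / d_j`; generality is the `d_j/m`-weighted sum over ants.
  Vulnerability is the row analogue. For a symmetric square matrix the two
  coincide; both are invariant under row/column permutation.
* **H2′** — network specialization. `H2 = −Σ p_ij ln p_ij` over positive
  cells with `p_ij = a_ij/m`; `H2′ = (H2max − H2)/(H2max − H2min)`, where
  the extrema are taken over non-negative *integer* matrices with the
  observed marginal totals, and the result is clamped to [0, 1]. It is
  undefined (NaN) when `m < 2`, when both sides have a single species, or
  when the marginals admit only one matrix (`H2max = H2min`), as happens
  for any single-row or single-column network.
* **Modularity** — Barber's bipartite
  `Q = (1/m) Σ_ij [a_ij − k_i d_j/m] δ(g_i, h_j)`, maximized over joint
  module assignments of plants and ants.

### H2 extrema heuristic

The exact integer-constrained entropy extrema are a combinatorial problem,
so `H2max`/`H2min` use heuristics, cached per marginal multiset:

* minimum: greedy descending-marginal filling (repeatedly allocate
  `min(k_i, d_j)` to the largest remaining row × column), plus a variant
  that pairs exactly matching `k_i = d_j` marginals first, plus six
  deterministic randomized-greedy restarts seeded from the marginals;
* maximum: proportional allocation `k_i d_j / m` rounded by
  largest-remainder while respecting both marginals, plus randomized
  largest-remainder fills;
* every candidate is then improved by 2×2 marginal-preserving transfers
  (single-unit moves toward evenness for the maximum, full-block moves
  toward concentration for the minimum) until locally optimal; the best
  candidate wins. Restart counts taper off for `m > 40`, where the swap
  improvement dominates.

The test suite compares these extrema against exhaustive enumeration of
*every* integer matrix for *every* marginal class up to 3×3 with total
≤ 12 (and a 2 000-case random battery during development found no
remaining gaps). Because a heuristic extremum is always attained by a
feasible matrix, any future shortfall can only narrow the envelope, and
H2′ stays in [0, 1] by clamping; the acceptance test reports such cases
rather than hiding them.

H2′ is exactly invariant under row/column permutation. Under integer
scaling of the whole matrix it is only *asymptotically* invariant: scaling
refines the feasible integer lattice, shifting the constrained extrema.
Measured deviations reach ~0.7 for m ∈ [8, 20) near-degenerate marginals
and fall below 0.06 for m ≥ 20; the property test asserts the m ≥ 20
regime plus exactness at the diagonal and marginal-product extremes.

### Modularity optimizer

Seeded label propagation: from several starts (all-singleton, all-one,
random assignments, and perturbations of the incumbent — iterated local
search), repeat best single-node moves to convergence followed by greedy
module merges until neither improves; keep the best partition over
restarts (default 20). The all-one-module start guarantees the returned
Q ≥ 0. A final zero-gain merge pass canonicalizes to the coarsest
partition attaining the same Q (so a single-interaction network reports
one module). The optimizer is deterministic given its seed and matches the
exhaustive set-partition maximum (feasible to 8 species, Bell(8) = 4140
partitions) on 100 seeded random networks in the acceptance suite.
Stochastic annealing optimizers for the same objective are not
bit-reproducible anyway; a seeded deterministic optimizer was chosen so
that reports regenerate exactly.

### Herbivory and occupancy

Ordinal leaf damage in four categories (0%, <5%, 5–33%, >33% missing leaf
area) is summarized per tree as the leaf-count-weighted mean of category
midpoints (0, 2.5, 19, 66.5 — arithmetic midpoints of the class intervals;
configurable). Occupancy is occupied/censused per species and/or
elevation, with "uncertain" counting as occupied.

## Null models

**Rarefaction prediction bands.** Occupied, identified records at the
pooled reference elevations (default: the two lowest, 700 and 800 m)
become an event multiset. For each target elevation, events are subsampled
*without replacement* to the observed abundance; each replicate network's
metrics are computed, and the 2.5/97.5 percentiles (linear interpolation
between order statistics) over defined replicates form the band (default
1000 replicates). Replicates with undefined metrics are counted and
dropped; bands with > 50% undefined replicates are flagged unreliable.
Each elevation draws from its own RNG stream keyed by (seed, elevation),
so adding an elevation never changes another's band. Band width shrinks to
zero as the target size approaches the pool size. Percentiles rather than
a normal approximation: standard for resampling prediction intervals and
bit-reproducible under seed.

**Marginal-preserving null for H2′.** Since H2′ measures deviation from
marginal expectations, its null fixes both marginals exactly: tables are
drawn by sequential conditional multivariate-hypergeometric row fills (the
classic two-way-table randomization). The one-tailed Monte Carlo p-value
uses the add-one estimator `p = (1 + #{null ≥ obs})/(N + 1)` (the
direction of interest is specialization *greater* than random; a
two-sided option exists). All null draws share the observed marginals, so
the entropy extrema are computed once per test; H2 values are rounded to
12 decimals before comparison so equal count multisets tie exactly. The
acceptance suite verifies exact marginal preservation, agreement of 2×2
table frequencies with the exact hypergeometric distribution, and
uniformity of p-values when the observed table is itself a null draw.

## Trend tests

Per metric, elevations with defined values enter either:

* **AIC-selected OLS** — degree 1 vs 2 on (optionally transformed) values,
  `AIC = n ln(RSS/n) + 2k` with `k = degree + 2` (intercept, slopes, error
  variance); constants cancel in the comparison, RSS below `1e−12 × TSS`
  counts as exact so the penalty prefers the simpler model. F, r², p from
  standard OLS theory (elevation is centred and scaled by 100 m for
  conditioning; fit statistics are invariant to this). Log transforms of
  non-positive values raise an error naming the offending elevation.
* **Hoeffding's D** — classical scaled statistic from midranks R, S and
  bivariate ranks Q (ties credit ½ per coordinate, ¼ for double ties):
  `D = 30[(n−2)(n−3)D1 + D2 − 2(n−2)D3] / [n(n−1)(n−2)(n−3)(n−4)]`.
  Requires n ≥ 5; constant input yields D = 0 with a warning. For untied
  data D equals the brute-force 5-tuple-kernel U-statistic exactly (tested
  to 1e−12 for all n ≤ 12); with ties the midrank counting formula is the
  convention itself — it is *not* a distinct-index U-statistic, because
  the `(Q−1)(Q−2)` products square the fractional tie credits — and tied
  inputs are tested against an independently coded direct-count
  implementation. p-values come from a permutation null (permute y,
  add-one estimator, one-tailed on large D) rather than the classical
  asymptotic table: at the n ≤ 10 typical of elevational designs the
  asymptotic null is unreliable, so tabled p-values are reproduced in
  distribution, not digit by digit.

The pipeline's default metric → method mapping: connectance → √ +
regression; generality → log + regression; richness → untransformed
regression; vulnerability, H2′ and modularity → Hoeffding's D.

## Synthetic community generator

The generator emulates the census design the analysis assumes; its
defaults are the study conditions used throughout the tests and the
acceptance script.

* **Design**: 10 transects at 100 m intervals, 700–1600 m a.s.l.; 23 plant
  and 10 ant species.
* **Ranges**: each species has a Gaussian elevational kernel (SD drawn
  lognormally around 200 m, ±25% log-scale) hard-truncated at 3 SD, so
  species genuinely drop out and communities turn over — without
  truncation, abundance decline alone cannot produce turnover. Range
  centers are drawn over the padded gradient with a Beta(1, 2.2) skew
  toward low elevations, reproducing declining richness upslope.
* **Abundance**: individuals per plant species per transect are Poisson
  with mean `peak × kernel(e) × 0.82^((e−700)/100)`; species peaks are
  lognormal around 8 per transect. This yields ~300 occupied trees per
  realization, richness falling from ~18 plants/9 ants at 700 m to below
  5/4 at 1500 m, and a mostly empty top transect.
* **Occupancy**: each individual is independently occupied with a
  per-elevation probability, default declining linearly 0.72 → 0.45 —
  matching occupancy near 60–72% for common lowland hosts with partner
  scarcity upslope.
* **Partner choice**: exactly one resident ant per occupied tree, drawn
  once per tree from weights (plant's affinity) × (ant's kernel at that
  elevation) — preference times local availability; ants outside their
  range are never drawn. Affinities are gamma draws exponentiated by the
  specialization exponent γ (default 2.5) and renormalized: γ = 0 gives
  uniform partner use, large γ concentrates each plant on one ant. γ
  declines by 0.25 per 100 m (floored at 0), emulating reduced choosiness
  where partners are scarce; this shift, with availability weighting, is
  what drives mean H2′ downward and lets one widespread ant dominate
  high-elevation networks. If an occupied draw occurs where no ant kernel
  is positive, the tree is recorded as unoccupied (no colonists).
* **Uncertain ants**: 8% of occupied records are relabelled "uncertain"
  (≈ the fraction of residents not collected in such censuses), to
  exercise the exclusion rule.
* **Herbivory**: per tree, leaf counts over the four damage categories are
  multinomial from a cumulative-logit model with cut-points (0.4, 2.0,
  4.0) shifting by 0.15 logits per 100 m — mean damage ~5% at the bottom
  of the gradient rising toward ~8–10% at the top.
* **Schema fidelity**: heights (lognormal, capped at 15 m — the
  understorey census ceiling) and DBH (lognormal) are recorded but feed no
  in-scope statistic. One categorical draw per tree: no colony dynamics,
  no within-plant succession, no within-transect spatial structure, no
  honeydew/coccid modelling.

Two scenario presets frame the central inference. `abundance_only()`
flattens every range (width 10⁵ m) and freezes γ, so higher-elevation
communities are true rarefied copies of the lowland one; observed
high-elevation metrics then fall inside their rarefaction bands.
`with_turnover()` (the defaults) adds range truncation and the γ shift;
high-elevation connectance/generality then escape their bands in the
majority of seeds, mean H2′ falls and mean connectance rises with
elevation. This contrast is the headline acceptance test.

**What passing tests do and do not show.** The generator produces
independent Poisson individuals, independent occupancy, and a stationary
preference structure; real censuses have spatial clustering, colony-level
processes, observation error and phylogenetic structure in preferences.
Passing the recovery tests therefore shows the *pipeline* distinguishes
abundance effects from reorganization when the data-generating process
matches its assumptions — not that any particular field system does.

## Reproducibility and problem sizes

Every stochastic step takes a seed; derived streams are keyed as
`(seed, purpose, elevation)`, so identical configuration + seed gives
byte-identical tables, and regenerating metrics from dumped incidence
matrices reproduces the direct run exactly. Default analysis sizes are
1000 band replicates, 1000 null draws and 10 000 permutations (20
modularity restarts for observed networks, 5 for band replicates). The
test and acceptance runs use reduced sizes chosen for quick iteration
(e.g. 200-replicate bands, 200-draw calibration nulls over 400 cases, 50
seeds for the scenario contrast); all checks are Monte Carlo bounds with
3-SE slack at those sizes.

## Known limitations

* H2 extrema and modularity are heuristic optima; both are oracle-checked
  exhaustively only where enumeration is feasible (small matrices, ≤ 8
  species).
* H2′ scale invariance is asymptotic in m (see above), an intrinsic
  property of integer-constrained extrema.
* Hoeffding p-values are permutation-based; they converge to, but do not
  equal, the classical asymptotic values.
* Prediction bands condition on the pooled community actually observed;
  they do not propagate uncertainty in the pool itself.
* The cumulative-logit herbivory model and the occupancy curve are
  phenomenological conveniences, not mechanistic models.
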