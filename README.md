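# antplant

Quantitative analysis of ant–plant protection mutualism networks along
elevational gradients.

Terrestrial ant-plants (myrmecophytes) house ant colonies in domatia and
receive protection in return. Censusing every occupied tree along a
mountainside yields, at each elevation, a quantitative bipartite network:
an integer matrix `a_ij` counting plant individuals of species *i* occupied
by ant species *j*. Two questions drive the analysis this package
implements for community ecologists working with such censuses:

1. **How does network architecture change with elevation?** Computed from
   first principles per elevation: *connectance* (realized fraction of
   possible links), weighted *generality* and *vulnerability* (effective
   number of plant partners per ant species and vice versa, via the
   exponential Shannon entropy of the matrix columns/rows weighted by
   marginal totals), network specialization

   `H2' = (H2max − H2) / (H2max − H2min)`,

   where `H2 = −Σ p_ij ln p_ij` is the interaction entropy and
   `H2max`/`H2min` its heuristic extrema over all integer matrices sharing
   the observed marginal totals (0 = random partner use, 1 = maximal
   specialization), and Barber's bipartite modularity

   `Q = (1/m) Σ_ij [a_ij − k_i d_j / m] δ(g_i, h_j)`,

   optimized by seeded label propagation with local moves and module merges.

2. **Is the change real reorganization, or just fewer ants?** Abundance
   declines with elevation, and small networks mechanically shift most
   metrics. The package separates the two with *rarefaction prediction
   bands*: the two lowest-elevation communities are pooled and repeatedly
   subsampled without replacement down to each higher elevation's abundance;
   the 2.5/97.5 percentiles of each metric over the replicates form a 95%
   band. Observed values outside their band indicate reorganization beyond
   the abundance effect. Observed `H2'` is additionally tested against a
   marginal-preserving Monte Carlo null (Patefield two-way-table
   randomization), and elevational trends are tested with AIC-selected
   linear/quadratic regression or Hoeffding's D (a rank-based dependence
   statistic robust to non-monotone trends), with a permutation null.

Because census data of this kind are rarely deposited, the package includes
a first-class synthetic community generator that emulates the census
structure such studies assume — overlapping truncated-Gaussian elevational
ranges, declining abundance and richness, exactly one resident ant per
occupied tree, preference-driven partner choice with tunable
specialization, and ordinal herbivory damage increasing upslope — so every
stage of the pipeline is testable end to end.

## Worked example

```python
import antplant as ap

model = ap.ElevationalNetworkModel.from_simulation(seed=1)
results = model.fit(seed=1, band_replicates=200, n_null=500, n_perm=2000)
print(results.metrics.round(3).head(4).to_string())
```

```
             plant_richness  ant_richness  connectance  generality  vulnerability  h2_prime  modularity_q   m
elevation_m
700.0                    17             8        0.265       4.165          2.145     0.566         0.546  75
800.0                    19             8        0.211       3.625          1.789     0.640         0.615  62
900.0                    14             9        0.230       3.141          2.528     0.466         0.564  54
1000.0                   14             8        0.205       3.061          1.996     0.464         0.598  31
```

Each row is one elevation: at 700 m, 75 occupied trees connect 17 plant and
8 ant species; 26.5% of possible links are realized and partner use is
strongly non-random (`H2' = 0.57`). Abundance, richness and the average
number of partners all fall with elevation. The Monte Carlo test confirms
the specialization is significant against random partner choice given
species frequencies:

```python
print(results.null_tests.round(4).head(3).to_string(index=False))
```

```
 elevation_m   metric  observed     p    tail  n_null
       700.0 h2_prime    0.5657 0.002 greater     500
       800.0 h2_prime    0.6396 0.002 greater     500
       900.0 h2_prime    0.4658 0.002 greater     500
```

and the trend tests quantify the elevational gradient (connectance is
square-root transformed, generality log transformed; vulnerability, `H2'`
and modularity use Hoeffding's D):

```
        metric     method transformation  degree  statistic     r2      p  n
plant_richness regression           none     1.0   131.7743 0.9428 0.0000 10
  ant_richness regression           none     2.0    99.0096 0.9659 0.0000 10
   connectance regression           sqrt     2.0    10.8307 0.7558 0.0072 10
    generality regression            log     1.0   168.4248 0.9547 0.0000 10
 vulnerability  hoeffding           none     NaN     0.2123    NaN 0.0205 10
      h2_prime  hoeffding           none     NaN    -0.0357    NaN 0.6082  8
  modularity_q  hoeffding           none     NaN    -0.0556    NaN 0.7771 10
```

`results.bands` holds the rarefaction prediction bands,
`results.outside_band` flags each observed metric against its band,
`results.sensitivity_trends` repeats the trend tests without the topmost
elevation, and `results.summary()` prints the whole report.
`results.save("outdir")` writes every table (CSV), the per-elevation
incidence matrices (TSV) and the run metadata.

The same pipeline runs from the shell:

```bash
antplant simulate --seed 1 --out census.csv
antplant all --census census.csv --out-dir report --seed 1
```

with subcommands `simulate`, `networks`, `metrics`, `bands`, `nulltest`,
`trends`, `report` and `all`, plus `--include-uncertain` /
`--drop-top-elevation` sensitivity flags.

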