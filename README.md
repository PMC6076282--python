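# markcorr

Marked point-pattern analysis of **conspecific distance-, density- and
aggregation-dependence (DDD)** of tree-level ecosystem services — seed
production and above-ground biomass (AGB) — in large, sparse tropical tree
populations such as Brazil nut (*Bertholletia excelsa*) stands spread over
polygonal harvesting concessions.

The package is for ecologists who have (or want to simulate) a tree
inventory — planar coordinates, DBH, a per-tree productivity estimate, and
concession polygons — and want to ask: *does a tree's seed production or
biomass depend on how close, how many, and how clumped its conspecific
neighbours are?* And: *how badly do those dependences bias plot-based,
area-scaled assessments of productivity at different evaluation-plot sizes?*

## The statistics

Marks are first normalized by the mean of all trees in the same concession,
so `1` means "average for its concession". Four mark correlation functions
are computed over distance bins `[r − h, r + h]` (bandwidth `h`) or
cumulative radii `r`:

1. **Nearest-neighbour mark mean** — mean normalized mark of trees whose
   nearest conspecific sits in the bin. Values `< 1`: trees with neighbours
   at that distance under-perform their concession average.
2. **Schlather's correlation** — Pearson correlation between the marks of
   (focal, nearest-neighbour) pairs in the bin; a mark analogue of Moran's I.
3. **Density correlation** — Pearson correlation between a focal tree's mark
   and its number of conspecific neighbours within `0..r`.
4. **Aggregation correlation** — Pearson correlation between a focal tree's
   mark and the Clark–Evans index of its neighbourhood,
   `CE = d̄ / E(d) = 2 d̄ √ρ`, where `d̄` is the mean nearest-neighbour
   distance among neighbourhood members and `ρ` the concession density
   (trees·m⁻²). `CE = 1` under complete spatial randomness, `< 1` for
   aggregated, `> 1` for regular spacing.

Edge corrections: functions 1–2 drop trees closer to the concession boundary
than to their nearest neighbour; functions 3–4 use only focal trees at least
`r` from the boundary, and neighbourhood members closer to the circumference
than to their nearest fellow member are excluded from `d̄`.

Significance is assessed against a **mark-shuffling null model**: 199 random
permutations of the marks over the trees, with pointwise envelopes at the
5th-lowest/5th-highest values (the 2.5th/97.5th percentiles); observations
strictly outside the envelope are flagged.

The **plot-size experiment** rasterizes the landscape at a ladder of grid
cell sizes (arc-seconds or meters), compares per-hectare *measured* (sum of
marks per cell) against *expected* (tree count × grand mean) values by
linear regression, and reports the slope (accuracy) and R² (precision) per
cell size, plus a distance-binned correlogram of the residuals.

Because the motivating inventories are not publicly deposited, the package
ships a **synthetic-data generator** whose presets encode the study
conditions (concessions of 16–4,575 ha, ~0.53 trees/ha, DBH ≥ 10 cm,
right-skewed seed marks averaging ~30 kg/tree, AGB from a diameter-only
pantropical allometric model with wood density 0.59 g cm⁻³, lata-to-kg
conversion at 11.66 kg) with configurable distance/density/aggregation
effects on the marks.

## Worked example

```python
import markcorr as mc

pattern = mc.generate_dataset(mc.scenario_presets()["unimodal"], seed=42)
analysis = mc.MarkCorrelationAnalysis(pattern, mark="seed")
res = analysis.fit(scheme="near_5", envelope=mc.EnvelopeConfig(n_sim=199, rng_seed=42))
print(res.summary())
```

```
Mark correlation analysis of seed (normalized marks)
trees used: 5017
nearest-neighbour edge rule dropped 7.6% of trees
envelopes: 199 mark shuffles, rank 5 (pointwise level 0.050, scope global)
  f1_nn_mean: 15 bins, 11 significant
  f2_schlather: 15 bins, 4 significant
  f3_density: 35 bins, 20 significant
  f4_aggregation: 35 bins, 4 significant
```

The `unimodal` preset plants a depression of seed production below 30 m and
an elevated plateau at 50–90 m; the fitted nearest-neighbour mark mean
recovers exactly that shape (`res.significant_bins("f1")`):

```
   r  statistic  envelope_lo  envelope_hi
 5.0   0.633320     0.806244     1.172801
15.0   0.626857     0.882407     1.131294
25.0   0.693970     0.903847     1.104869
35.0   0.777410     0.922912     1.064118
55.0   1.134215     0.923938     1.075177
65.0   1.097949     0.918210     1.063006
```

Bins at 5–35 m sit *below* the envelope (near neighbours depress
production), bins at 55–85 m *above* it. `res.plot("f1")` draws the familiar
dots-and-envelope figure.

The plot-size experiment on the same landscape:

```python
sc = mc.PlotScaling(pattern, "seed").fit(
    mc.ScalingConfig(cell_sizes=(100., 200., 500., 1000., 2000.), units="m"))
print(sc.summary())
```

```
Plot-size scaling of seed (through_origin)
 cell_size  cell_area_ha  slope  slope_lo  slope_hi     r2  n_cells
       100             1 0.9565    0.9409     0.972 0.6129     9195
       200             4 0.9744    0.9512    0.9976 0.7532     2218
       500            25 0.9914    0.9582     1.025 0.9147      322
      1000           100 0.9846    0.9387      1.03 0.9638       70
      2000           400 0.9859    0.8928     1.079 0.9802       12
```

Accuracy (slope) is biased low at small plots and approaches 1 as cells
grow; precision (R²) rises from 0.61 at 1 ha toward 0.98 at 400 ha.

A CLI mirrors the library: `markcorr simulate`, `functions`, `envelopes`,
`scaling`, `run-all`, `report` (see `markcorr --help`).

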