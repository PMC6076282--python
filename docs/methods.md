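# Methods

## Data model

A *marked point pattern* is a set of trees with planar metric coordinates
(meters), each belonging to one polygonal concession and carrying two marks:
annual seed production (kg/tree) and above-ground biomass (kg). All spatial
statistics are strictly per concession: nearest-neighbour searches, neighbour
counts and edge rules never cross a concession boundary, and marks are
normalized by the concession mean. The per-concession convention follows from
the normalization itself — concessions are spatially disjoint management
units with their own harvesters, densities and growing conditions, and the
point of the normalization is to remove exactly those unit-level differences
before pooling. Inputs in geographic lon/lat are refused by the pattern
container; a hand-written standard Transverse Mercator forward projection
(WGS84 series, sub-meter accuracy within a zone; default UTM 19S) is
provided to project geographic inputs first.

Trees without a DBH measurement carry seed marks only; AGB analyses exclude
them up front, report the exclusion count, and recompute all spatial
structure on the remaining trees (the exclusion changes nearest-neighbour
relations, so it must happen before, not after, the geometry).

## Allometry

Seed production arrives from harvesters in *latas* (tin cans, ≈ 11.66 kg of
fresh in-shell seed each); conversion is linear and exact. AGB uses the
diameter-only pantropical model
`ln(AGB) = −1.803 − 0.976·E + 0.976·ln(ρ) + 2.673·ln(D) − 0.0299·ln(D)²`
(AGB kg, D cm, wood density ρ g·cm⁻³, environmental stress E). Defaults are
ρ = 0.59 (species-level value for Brazil nut) and E = 0. The inventories the
package targets record no tree heights, which is why the diameter-only form
is the default; E for any given region is rarely known precisely, so it is
exposed as a parameter rather than fixed. The whole coefficient vector is
replaceable, and no downstream statistic depends on the specific equation.

## Mark correlation functions

Distance bins are closed intervals `[r − h, r + h]`; a distance on a shared
boundary is assigned to the lower bin (deterministic tie-break). Named
schemes: bandwidths 1.5/5/10 m with contiguous bins (center step `2h`) up to
150 m; bandwidths 3/10/20 m over 150–350 m; cumulative radii 10, 20, …,
350 m. For `h = 10` the last near bin ends at 140 m (a center at 145 m would
need a half-bin); the contiguous-step rule is applied uniformly rather than
forcing a final overlapping bin.

* **f1 (nearest-neighbour mark mean)** averages normalized marks of trees
  binned by nearest-neighbour distance. Empty bins are flagged `empty`, not
  reported as 0.
* **f2 (Schlather)** is the Pearson correlation over ordered
  (focal, nearest-neighbour) mark pairs per bin. Ordered pairs mean mutual
  nearest neighbours contribute twice — per-tree symmetric weighting; a
  `unique_pairs` switch collapses to unordered pairs. Bins with < 3 pairs
  are flagged `unstable` (in sparse far bins the statistic is noise);
  zero-variance bins are undefined and flagged, never silently 0.
* **f3 (density correlation)** correlates focal marks with cumulative
  neighbour counts within `r`, restricted to focal trees ≥ `r` from the
  boundary.
* **f4 (aggregation correlation)** correlates focal marks with the
  neighbourhood Clark–Evans index `2·d̄·√ρ`. `d̄` is the mean
  nearest-neighbour distance *among members of the disc* (focal excluded),
  after excluding members closer to the circumference than to their nearest
  fellow member; `ρ` is the focal tree's concession density converted to
  trees·m⁻² so the index is dimensionless with `d̄` in meters. The index
  expectation is written through the ratio form `d̄/E(d) = 2·d̄·√ρ`, i.e.
  `E(d) = 1/(2√ρ)`, the standard Clark–Evans expectation under complete
  spatial randomness.

Normalized marks are used in all four functions. The rationale for extending
the normalization to f3/f4: without it, between-concession mean differences
in both marks and density would generate spurious mark–crowding correlations
that have nothing to do with neighbourhood-scale biology. A `--raw-marks`
flag exists for sensitivity analysis.

### Known bias of the circumference exclusion

The member-level edge rule (drop members closer to the circumference than to
their nearest fellow member) is a border-method correction. It removes the
upward bias of truncated neighbourhoods but introduces a small *downward*
selection bias on `d̄` (points with large nearest-neighbour distances are
preferentially excluded), of order `E(d)/r`. On simulated CSR the mean index
at `r = 100 m` is ≈ 0.96 at 50 trees/ha and ≈ 0.98 at 200 trees/ha rather
than exactly 1. This is a property of the estimator as defined, not of the
implementation; the permutation null model is unaffected because observed
and null statistics share the same geometry.

## Null model and envelopes

The null hypothesis is mark-location independence: marks are normalized
once, then permuted uniformly over all trees (`global` scope; a
`within_concession` scope is available as a stricter conditional null that
exactly preserves each concession's multiset). With `n_sim = 199` replicates
and rank 5, the pointwise envelope bounds are the 2.5th/97.5th percentiles
and the two-sided level is `2·rank/(n_sim+1) = 0.05`. Significance is strict
exceedance of the closed envelope. The test is pointwise per bin; no
multiple-testing correction across bins is applied, and simultaneous
(global-rank) envelopes are deliberately out of scope — users should expect
~5% of bins flagged under the null.

Replicate streams are spawned from a single master seed
(`SeedSequence.spawn`), so results are independent of evaluation order and
the full pipeline is bit-reproducible from (dataset seed, envelope seed).
Re-normalization after each shuffle is *not* performed; under global
shuffling the per-concession means of permuted marks fluctuate slightly
around 1, which is part of the null being simulated.

## Plot-size scaling

Each concession is gridded from the min corner of its bounding box with
half-open cell membership; cells not fully inside the window (coverage
< 1.0 by default) are dropped. Arc-second cell sizes are converted at a
reference latitude (default 12°S): north–south height
`= arcsec·(π/648000)·R_earth`, east–west width additionally `× cos(lat)` —
at 12°S a 3.33″ cell is ≈ 1.03 ha. Measured = Σ marks per cell; expected =
tree count × grand mean over all trees pooled.

The regression of measured-per-ha on expected-per-ha defaults to
through-the-origin (expected 0 structurally implies measured 0), keeping
empty cells; `with_intercept` mode is provided and drops empty cells so
zero-inflation does not dominate the fit. R² is uncentered in through-origin
mode. Slope CIs are 95% Wald intervals from the OLS standard error
(statsmodels). Residual spatial autocorrelation is checked with a
distance-binned Moran-type correlogram (`mean(z_i z_j)/var(z)` over cell
pairs per distance bin) with a 99-permutation pointwise envelope — an
explicit simplification of spline correlograms.

## Synthetic data generator

The generator emulates the study conditions: 10 rectangular concessions with
areas drawn log-uniformly from 16–4,575 ha (rescaled so the landscape holds
~5,000 trees at 0.53 trees/ha in the presets), tree locations from a
homogeneous Poisson process or a Thomas cluster process (parents at
intensity `density/μ`, Poisson(μ = 5) offspring, Gaussian σ = 20 m
dispersal, oversampled and thinned back to the target count — thinning
preserves cluster structure), DBH lognormal (meanlog ln 80 cm, sdlog 0.35,
truncated at the 10 cm inventory threshold, giving mean AGB ≈ 10 t/tree),
and marks built multiplicatively:

    seed = baseline_c · g(nn_dist) · exp(−β·count(r_eff)) · (1 + γ·(CE − 1)) · noise

with a per-concession lognormal baseline (sdlog 0.35, mimicking
between-concession mean shifts), a piecewise-linear distance response `g`, a
crowding response, an aggregation response computed with the *same*
neighbourhood definition as the analysis (so recovery tests are a genuine
round trip, not a tautology), and lognormal noise (sdlog 0.76, CV ≈ 0.9,
giving the right-skewed 0–360 kg per-tree range around a ~30 kg mean).
Multiplicative structure keeps marks non-negative by construction.

Presets: `null` (no effects — the exchangeability the envelope test
assumes), `fine_negative` (g = 0.7 below 30 m), `unimodal` (depression
below 30 m, 1.25× plateau at 50–90 m, decline beyond 150 m), `ddd_full`
(Thomas clustering plus all three mark effects, β = 0.1 at 100 m, γ = 0.5
at 100 m).

What the generator does **not** emulate: irregular concession shapes,
inhomogeneous within-concession density, genetic/kinship structure,
pollinator movement, measurement error in coordinates, and the empirical
correlation between DBH and seed production. Passing recovery tests
therefore show the *statistics* detect the effects they target at realistic
sample sizes and noise levels — not that any particular field dataset
contains such effects.

## Problem sizes and numerical choices

Calibration and recovery checks use: ~5,000-tree landscapes for effect
recovery (20 replicates) and null mean-calibration; 400 landscapes of ~600
trees for the per-bin type-I-error check (the wider replication narrows the
binomial band enough for a per-bin assertion to be meaningful); a
200 trees/ha CSR pattern for the Clark–Evans calibration, where a 100 m
neighbourhood holds ~300 members and the `E(d)/r` exclusion bias is far
inside the ±0.05 calibration band. Oracle-equivalence tests compare every
spatial statistic against independent brute-force loops at `n ≤ 500` to
1e−10. Nearest-neighbour ties are broken by smallest tree id; coincident
trees within a concession are rejected as errors.

## Limitations

* Envelope tests are pointwise; bin-wise significance counts overstate
  landscape-level evidence.
* The Clark–Evans neighbourhood index is undefined in sparse neighbourhoods
  (< 2 usable members) and slightly negatively biased (see above); at field
  densities of ~0.5 trees/ha it only stabilizes at radii of hundreds of
  meters.
* Through-origin R² is not comparable with intercept-model R²; the package
  reports whichever mode is configured and both in the demo pipeline.
* No inhomogeneous-intensity corrections, cross-species statistics, or
  global envelope tests.
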