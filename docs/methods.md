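# Methods

This note documents the models implemented in `heatland`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Analysis grid and ranges

The analysis lattice is an abstract equal-area grid (default cell edge
24.125 km, cell area 582.015625 km²). Real-world deployments would build
such a grid in a Behrmann projection and rasterize range polygons onto it;
this package deliberately starts one step later, from per-cell overlap
fractions, so no CRS machinery or polygon geometry is involved. Two
rasterization rules apply:

* a species whose polygon is smaller than one grid cell keeps **every**
  touched cell;
* otherwise cells with overlap below 10 % are dropped. Overlap exactly
  equal to the threshold is kept — the exclusion rule is a strict "< 10 %".

A large-ranged species whose overlaps all fall below the threshold would
otherwise end up rangeless; it keeps its single best cell and a warning is
logged. This keeps every species analysable, at the cost of a slightly
generous range for a handful of edge cases.

## Extreme heat events

**Thermal limit.** *T\** per species and climate model is the spatial
maximum over range cells of the per-cell 99th percentile of daily maximum
temperature over the 1950–2005 baseline. The percentile uses linear
interpolation between order statistics (numpy's default); the method is
configurable in `HeatEventConfig` and pinned in the tests.

**Events.** An event is a maximal run of consecutive days with Tmax
strictly above *T\**, of length ≥ 6 days ("more than five consecutive
days"; five exactly does not qualify, and exceedance is strict). All
series use a 365-day no-leap calendar — the convention of the daily
downscaled CMIP6 products this emulates — which keeps day indexing and
synthetic generation trivial.

**Per cell-year metrics.** Frequency = number of events; duration =
longest single event in days; intensity = maximum °C exceedance over event
days. The alternative operationalisations (total event days; mean
exceedance) are one flag away (`duration_metric="total"`,
`intensity_metric="mean"`) because the literature uses both; defaults are
the max-type definitions. Runs are evaluated within calendar years: a run
crossing December 31 is split at the boundary. This is a documented
simplification — per-cell-year bookkeeping forces a convention, and
splitting is the only one that keeps the metrics a function of the year's
own days.

**Suitability.** A future cell-year is unsuitable when any of the three
metrics strictly exceeds the species-wide baseline maximum of that metric
(maximum over all range cells and baseline years). Equality stays
suitable; this makes the baseline period self-consistent by construction
(a species can never be flagged in its own baseline, which the test-suite
verifies end-to-end). Binary flags from the climate-model ensemble are
combined by the median, i.e. a strict majority; an odd model count is
required and enforced. Years before 2020 are treated as climatically
suitable everywhere. An alternative — taking medians of the underlying
metrics before thresholding — was considered and rejected as the default
because the binary-majority reading follows the stated per-model
suitable/unsuitable classification most directly.

## Suitable area and exposure

Combined per-cell suitability is the product of the binary climate flag
and the fractional preferred-habitat cover — a deliberate asymmetry
(climate is all-or-nothing per cell, land use is fractional) that tends to
weight heat more heavily, and is flagged as such below. Habitat cover is
**not** renormalised for the water/ice remainder of a cell: the fractions
carry absolute land-area semantics.

`SA_2015` uses the 2015 land-use layer with climate assumed suitable
everywhere. Species with `SA_2015 = 0` (no preferred habitat anywhere in
the range at baseline) are excluded from percent-change statistics and
logged.

The extinction rule is absorbing and idempotent: from the first year with
zero suitable area the species stays at zero. Before extinction any cell
recolonises instantly when its land use returns to a suitable class,
regardless of adjacency — an explicit best-case assumption which
overestimates persistence for dispersal-limited species.

The signed percent change lives in [−100, 100): losses come from
SA_y/SA₂₀₁₅ − 1, gains from 1 − SA₂₀₁₅/SA_y. The 0–200 index is the
signed value plus 100; the shift is the only reading under which the
stated 0–200 range is consistent with the two branch equations, and both
the signed and the shifted values are emitted. The exposure fraction is
max(0, −%change)/100.

**Driver modes.** `climate_only` re-weights climate flags by the *2015*
habitat fractions; `landuse_only` ignores climate flags. Because the
climate-only counterfactual freezes habitat at 2015, combined SA is
guaranteed ≤ land-use-only SA for every species-year, but can exceed
climate-only SA when land-use *gains* occur on climate-suitable cells —
that is precisely the compensation effect low-pressure scenarios show.
For species that cannot gain habitat under a given scenario the full
dominance holds (combined SA ≤ both counterfactuals, combined exposure ≥
the worst single-driver exposure), and the test-suite asserts exactly that
split rather than a blanket inequality that the model structure does not
support.

**Attribution.** Among species whose combined exposure reaches a threshold
(default 0.5), the class is `heat` if the climate-only counterfactual
alone reaches the threshold, `landuse` in the reverse case, `both` if each
does individually, and `combined_only` if neither does. `both` is kept as
its own class rather than forced into either driver; shares "due to heat"
should be read as heat/(all attributed), with `both` tabulated separately.

## Per-cell summaries

For each cell holding at least one species, over an end-of-century window
(default the 2091–2100 mean, against 2015):

* mean land-use-driven change: per species present, the percent change of
  its preferred-habitat fraction in that cell (window mean vs. 2015, same
  gain/loss equations as SA), averaged over species. The window mean is
  computed as base + mean(deviations) so a static world yields exactly 0.
* proportion climate-exposed: share of species present whose ensemble
  flag in that cell is unsuitable in at least one window year
  (`window_rule="majority"` switches to a majority of window years).
  Species extinct before the window count as present and exposed — the
  map describes exposure of current ranges, not residual occupancy.

The 3×3 bivariate classes use explicit, admittedly arbitrary default
edges (land-use ±5 %, climate proportion 0.25/0.5 — no published edges
exist to adopt); boundary values fall into the lower bin. A cell with no
change and no exposure therefore maps to (row 0, col 1): lowest climate
bin, neutral land-use bin.

## ZOIB exposure model

End-of-century exposure fractions have genuine mass at 0 (untouched
species) and 1 (total loss, including extinctions, which enter with
y = 1). The zero-one inflated beta model is the standard conditional
parameterisation: logit models for P(y=0) and P(y=1 | y>0), a beta
density with logit-linked mean μ and a single shared precision φ on the
interior. Covariates are an intercept, log₁₀ initial suitable area
(SA₂₀₁₅, km² — the package's operationalisation of "initial range size")
and Red List category as unordered indicators with LC as reference (an
ordinal-score coding is available). The pipeline stage fits **all**
analysed species rather than only those that lost area: restricting to
losers removes every y = 0 by construction and forces the zero-inflation
component to a degenerate boundary; the loser-only subset remains easy to
fit via the standalone API on a filtered table.

Fitting is maximum likelihood (BFGS with the analytic score) from a
deterministic start: intercepts at the logits of the empirical masses and
the interior mean, zero slopes, φ = 1. Standard errors come from the
finite-difference Hessian of the negative log-likelihood at the optimum.
Non-convergence and boundary collapse (fitted masses beyond 0.999) are
flagged in the returned report, never raised. Because the likelihood
factorises, the joint MLE equals three separable fits; the test-suite
exploits this to cross-check the implementation against independent
logistic and beta regressions. Parameter recovery (n = 2000, 200
replicates) shows per-coefficient bias below 0.1 and ≈99 % coverage of
±3 SE intervals.

When the pipeline's species count cannot support the full design
(fewer than 5 observations per parameter), the stage automatically drops
the Red List terms, and below that bound it reports the fit as skipped.

## Synthetic worlds

The generator emulates the structure, not the magnitudes, of the global
inputs:

* **Land use**: per-cell 12-category compositions drawn from a Dirichlet
  over a land total of 0.85–1.0 (the remainder standing in for water/ice),
  then drifted annually: natural classes convert to annual cropland at a
  scenario rate (strongest, 0.4 %/yr, under the SSP3-like scenario),
  while the SSP1-like scenario reverses flow from cropland to secondary
  vegetation (−0.2 %/yr). Compositions never go negative and never sum
  above 1.
* **Climate**: Tmax = latitudinal base gradient (32 → 12 °C across rows)
  + 8 °C seasonal sinusoid + 0.1 °C/decade shared historical trend +
  scenario warming from 2015 (0.15/0.30/0.45/0.60 °C per decade for the
  RCP2.6/4.5/7.0/8.5-like scenarios, bracketing typical end-of-century
  outcomes) + AR(1) noise per pseudo-GCM (sd 2 °C, lag-1 correlation
  0.6). Noise and history are scenario-independent, so the 1950–2005
  baseline is identical across scenarios, as it must be.
* **Species**: contiguous blob ranges with log-normal sizes (medians 5/6
  cells for amphibians/reptiles vs. 12/14 for mammals/birds, σ = 0.7 on
  the log scale), taxon mix proportional to the real per-taxon species
  counts, habitat preferences weighted toward natural classes, and Red
  List categories tilted toward threat for smaller-ranged species.

Every draw descends from a single mandatory seed; identical configs give
byte-identical worlds. Ground truth (per-species thermal limits computed
directly from the generator's series, and analytic expectations for
designed species) is recorded in a sidecar.

Two designed worlds anchor the pipeline analytically. The **null world**
zeroes warming, land-use trends *and* noise — a stationary periodic
climate in which every future year replays the baseline, so the pipeline
must return exactly zero change for every species (verified to the bit).
The **half-loss world** puts one species on a flat-temperature grid with
spatially uniform, static, dyadic habitat fractions and confines strong
warming to exactly half the rows; the recovered exposure fraction must be
0.5 exactly.

What the synthetic tests do **not** show: realistic geography or
coastlines, CMIP6-faithful variance structure, land-use transition
matrices, range-shape realism, or the global headline magnitudes — those
depend on the real IUCN/LUH2/NEX-GDDP inputs, which the pipeline accepts
through the same interfaces (per-cell overlap fractions, 12-category
fractional layers, per-cell daily series) but which are outside this
package's scope.

## Problem sizes and budgets

Daily series are generated lazily per (scenario, model, cell) and never
held all at once. The shared test world is 15×15 cells, 50 species, 3
pseudo-GCMs and two scenarios over the full 1950–2100 daily record
(~55,000 days per series) — small enough for the whole suite to run in
under a minute on one core while still exercising every stage at full
temporal resolution. Desk-scale default configs (30×30, 200 species) run
in a few minutes; 5-GCM runs are the intended "full" setting.

## Known limitations

* Binary climate × fractional land use overweights heat relative to land
  use, as discussed above.
* Instant recolonisation and no dispersal limits make land-use losses a
  best case.
* The year-boundary split can break a single long event into two shorter
  ones, slightly deflating duration in both years.
* The IUCN mapping ships as an editable default (natural open habitats →
  non-forest, rural gardens → urban, caves and marine codes dropped);
  users with the published crosswalk should substitute it via the mapping
  argument.
* The bivariate bin edges are conventions, not estimates.
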