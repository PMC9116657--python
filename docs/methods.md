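# Methods

## The problem

A pyre site used over generations yields tens of kilograms of cremated
human bone, commingled and fragmented far beyond element-level
identification. Conventional MNI counting from repeated skeletal
landmarks grossly under-represents such deposits (a handful of
individuals against tens of kilograms of bone), so the quantitative
analysis works from weights: per-square weight recording during
excavation, weight-ratio indices, spatial density patterns, and a
demographic weight budget that converts total bone mass into a minimum
head count under explicit depositional assumptions.

## Data model

One record is a weighed lot: excavation square (letter row × numeric
column on a 25 cm grid), stratigraphic unit with optional cut label
(roman numerals I–IV or the surface label "roof"), size class (`lt20`,
`ge20`, `tooth`) and anatomical region (`cranial`, `postcranial`,
`tooth`, `undetermined`; teeth are weighed apart from the </> 20 mm
split, so `tooth` region and size class imply each other). Weights are
non-negative grams; duplicate (square, stratum, size class, region)
keys are rejected at load time with line numbers.

The default grid is 18 letter rows (A–R, all letters used) × 28
columns. Published grid codings do not always determine the exact cell
layout: the bounding box of A–R × 1–28 at 0.25 m is 31.5 m², while the
documented excavated surface of the reference site is 26 m² (an
irregular trench does not fill its bounding box). The loader emits a
`GridGeometryWarning` rather than silently reconciling the two; the row
alphabet and column count are constructor parameters.

Blank or unknown cut labels load as "no cut" rather than erroring,
because supplementary tables rarely state their cut coding completely.

## Indices

* Fragmentation index `FI = W_lt20 / W_ge20 × 100`; higher = more
  fragmented. A deposit-level or regional FI is **pooled** (ratio of
  summed weights) by default, because pooling is what reproduces
  deposit-level published values (e.g. shares of 76.6% and 22.5% give
  76.6/22.5 × 100 = 340.4, printed as 340); a per-square-mean variant is
  available via `method="mean"` since published regional "average"
  indices do not state which rule was used.
* CPC index `CPC = W_cranial / W_postcranial × 100`, computed on the
  identified > 20 mm weight. The identity
  `CPC/100 = share/(100 − share)` links it to the cranial share of
  identified weight.
* Zero denominators return a result flagged `defined=False` instead of
  raising, so index maps over sparse grids survive peripheral squares
  that contain a single size class.
* All values are carried at full precision; report rounding is half
  away from zero at one decimal, matching how such values are printed.

## Spatial analysis

Weight maps sum record weights per cell, optionally filtered to one
stratigraphic unit; a unit filter includes all its cuts plus the "roof"
surface layer, since published unit totals are comprehensive of both.
Transects are single rows/columns of the map; hotspots are the ranked
nonzero cells (ties broken lexicographically by row then column).
Core-region statistics (total, per-square mean, metric extent) are
computed for an explicit member set; a heuristic detector (smallest
rectangle containing all cells ≥ 10% of the map maximum, fraction
configurable) stands in when no delineation is supplied, because
published core extents state the rectangle, not the rule that produced
it.

Peripheral accumulations are connected components of nonzero non-core
cells (8-connectivity default, 4 available, via `scipy.ndimage.label`),
each with pooled weight and pooled FI. Published accumulation groupings
are sometimes visual rather than graph-connected (cells several rows
apart grouped as one "accumulation"); explicit member lists passed to
`region_stats`/`region_fragmentation` reproduce such groupings exactly.

## The weight-budget MNI model

Deaths are assumed to follow a fixed demographic unit: integer ratios
`r_c` over age/sex classes, default 1:1:2
(male:female:subadult), encoding a 1:1 adult sex ratio and ~50%
subadult mortality as typical of pre-industrial populations. Per-capita
contributions `m_c`:

* **primary mode** — the expected mass of a complete burnt skeleton:
  2,500 g (adult male), 1,800 g (adult female), 500 g (subadult,
  infant figure; a 1,000 g adolescent alternative is available).
  These are regional Bronze Age reference figures; modern cremations
  run 2–3 kg (males) and 1.5–2.5 kg (females).
* **residual mode** — `expected − collected`, with collected masses
  from reference urn weights: 1,695 g (male, Novale di Sotto) and
  1,443 g (female, Collalbo), giving residuals of 805 g and 357 g.

The solver computes `n = round(W / Σ r_c m_c)` and reports counts,
MNI, modelled mass and misfit. Rounding is **nearest, half-up** by
default: with the shipped scenarios, 63,555/5,300 = 11.99 → 12 and
63,555/1,476 = 43.06 → 43, which is the arithmetic the reference
analysis performs; floor would read "minimum" more literally (11 units)
and is exposed as an option rather than adjudicated. The solution is
exactly the misfit-minimising integer (verified against brute force in
the tests), is monotone in `W`, and is invariant to joint rescaling of
masses and observed weight.

**The subadult residual ambiguity.** The reference residual budget
prints the subadult term as "(500 g − 157 g)" yet its printed total
(63,468 g for 43/43/86 individuals) and MNI (172) are reproduced only
when the subadult per-capita residual is 157 g — the Frattesina
subadult urn average used directly, not subtracted. Both readings ship
as explicit scenarios (`salorno_hypothesis_b("reproduced")` with a
157 g override, `"printed"` with the literal 343 g); neither is
declared correct, and no code hides the discrepancy.

`compare_hypotheses` returns one solution per scenario and no verdict:
choosing between primary and residual deposition is an archaeological
judgement, not a numeric one.

The generational-capacity model is the complementary plausibility
check: a use-span of `S` years at generation length `G` and nuclear
families of `F` persons implies `S/G` generations and `S/G × F`
expected deaths (200 y, 25 y, 6 → 8 generations, 48 deaths — the same
order as the primary-deposition MNI).

## Synthetic deposit generator

The generator emulates the statistical structure the analysis assumes,
in three seeded stages (independent RNG streams spawned from one master
seed, so stages are separately reproducible):

1. **Community** — `generations × family_size` deaths (default 8 × 6 =
   48). Class assignment is deterministic at the death-structure ratios
   by default (the budget model's own assumption; a multinomial option
   exists). Skeleton masses are truncated-normal around the class
   means; default spreads are a quarter of the modern reference ranges
   (sd 250 g for adults, 125 g for subadults), since the references
   give ranges, not distributions.
2. **Fragmentation** — tooth mass is a fixed fraction (default 0.008)
   of body mass; the remaining mass splits into < 20 mm vs > 20 mm with
   a Beta-distributed small-fragment fraction of mean `F/(F+100)`
   (target index `F` = 340, concentration 50 by default; concentration
   0 gives the exact expectation); the cranial fraction of the > 20 mm
   mass is likewise Beta around 0.15.
3. **Deposition** — optional collection removes up to a per-class mass
   per individual, depleting the > 20 mm categories first (ossilegium
   selects the larger identifiable pieces), then < 20 mm, then teeth.
   Remaining category masses split into 20 equal lots each and scatter
   around the pyre centre by an isotropic 2-D Gaussian (sd 0.5 m — a
   pure implementation choice, as no dispersion parameter is published
   for such deposits), quantised to 25 cm cells and clipped to the
   nearest edge cell so mass is conserved exactly.

Problem sizes in the shipped tests: 48-individual deposits for
recovery and determinism checks, 20-individual deposits for centroid
recovery, up to 240 individuals for index convergence, 50 replicates
for solver recovery, and 1,000 random instances for the brute-force
solver cross-check.

What the generator does **not** emulate: combustion physics and
taphonomy (post-depositional fragmentation, trampling, bioturbation),
anisotropic or multi-pyre scatter, inter-annual variation in mortality,
and the irregular trench outline. Passing tests therefore demonstrate
internal consistency of the pipeline — conservation, parameter
recovery, index convergence — not that real deposits satisfy the
model's assumptions.

## Numerical choices and degenerate inputs

* Report rounding: half away from zero (not banker's), 1 decimal.
* Zero-denominator indices: flagged, not raised (see above); empty
  deposits make composition shares an error, since there is no total to
  share.
* Solver ties at exact half-units round up under `nearest`; ties in
  hotspot ranking break by (row, column).
* Scenario ratios are reduced to the smallest integer vector on
  construction, so unit counts are comparable across scenario
  phrasings.
* CSV reads use round-trip float parsing so write∘read is the identity
  on deposits, bit for bit.

## Known limitations

* The weight budget is deterministic arithmetic: no uncertainty
  propagation over class masses or collection weights beyond running
  alternative scenarios; no life tables.
* Per-cut (3-D) spatial structure is available only as filtering, not
  volumetric modelling; no geostatistics (kriging, Ripley's K).
* The automatic core detector and connectivity-based cluster detector
  are conventions, and published delineations should be passed
  explicitly when reproducing them.
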