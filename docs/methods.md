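# Methods

## Data model and survey geometry

The atomic unit is one measured stem (`TreeRecord`): cluster, plot,
habitat, protected-area flag, species, DBH (cm, stored to 0.1), and an
optional stem-form score. The sampling unit is a 1 ha square cluster of
four 0.1 ha (50 × 20 m) plots at its corners; plots are divided into four
25 × 10 m subplots. All stems with DBH ≥ 10 cm are measured over the full
plot and scored for stem form (SF1 straight / SF2 wavy / SF3 crooked);
stems with DBH in [5, 10) cm are censused only in one subplot, i.e. with
inclusion probability equal to the subplot's area fraction (0.25).

Density estimation corrects for this by an expansion factor of
1/`subplot_fraction` per small-stem record, so
`stems_per_ha = Σ w_i / (n_plots × plot_area_ha)`. Rarity, occurrence and
richness statistics deliberately use raw counts: the population-size
criterion ("abundance > 2") refers to recorded individuals, and the
richness estimators assume individual-level sampling, not weighted
counts.

All DBH intervals are half-open `[lo, hi)` so class boundaries (10, 20,
30, 40 cm) are never double-counted; a 10.0 cm stem belongs to the full
plot and to the 10–20 class. Species names are matched after trimming,
case-folding and collapsing internal whitespace; there is no fuzzy
matching, so the timber list must use the same binomials as the
inventory.

## Operationalization choices

* **Occurrence** (the protection-index unit) is a plot-level presence: a
  species seen in a plot counts once however many stems were recorded.
  The plot is the smallest unit with a consistent protected-area
  classification.
* **Geographic range** is proportional occupancy of surveyed clusters
  (plot-level occupancy is available via `range_unit="plot"`). Clusters
  are the spatially independent sampling locations; plots within a
  cluster are only 100 m apart. The denominator is every surveyed
  cluster; because an inventory file only shows units that held stems,
  `total_units` should be supplied explicitly when some surveyed units
  were empty. In the degenerate case of a one-unit survey, full occupancy
  is (correctly, if unhelpfully) "wide".
* **Population size** defaults to the species' maximum abundance in any
  single habitat ("somewhere large"); total-abundance mode is available
  (`abundance_scope="total"`).
* **Boundaries** follow the printed inequalities exactly: wide means
  occupancy *strictly* greater than 10 % (so exactly 10 % is narrow),
  large means abundance > 2 (so exactly 2 is small), various means > 1
  habitat.

## Rarity indices

The three continuous indices are implementation-defined: the framework
they come from is cited in the literature by name but without printed
formulas, so this package fixes its own forms and labels results as
index-version-specific:

* `gri = 1 − occupied_units / total_units`
* `hsi = 1 − (h − 1)/(H − 1)` for a study region with `H > 1` habitats
  (`hsi = 1` by convention when `H = 1`)
* `psi = 1 − log(1 + n) / log(1 + n_max)` (natural log; `n_max` is the
  abundance of the most abundant species in the run)
* `ri = (gri + hsi + psi)/3`

Each lies in [0, 1] with higher = rarer; `gri` is strictly decreasing in
occupancy and `psi` strictly decreasing in abundance, which is all the
classifier-independent analyses rely on. The log transform keeps `psi`
responsive at the scarce end where the ecology happens, rather than
letting the dominant species' tail compress it.

## Richness estimators

Bias-corrected Chao1: `Ŝ = S_obs + f₁(f₁−1)/(2(f₂+1))`, SE from the
standard bias-corrected variance

    var = f₁(f₁−1)/(2(f₂+1)) + f₁(2f₁−1)²/(4(f₂+1)²) + f₁²f₂(f₁−1)²/(4(f₂+1)⁴)

(zero when `f₁ = 0`). ACE uses the classical coverage form with rare
cutoff 10; when every rare species is a singleton the coverage estimate
is zero and ACE is undefined, so the implementation falls back to Chao1
with a warning, and the ACE estimate is clamped below at `S_obs` (an
extrapolative estimator below observed richness is uninterpretable). ACE
is reported without a standard error: several variance conventions are in
circulation and none is implemented here. Point estimates of both
agree with `vegan::estimateR` to ~1e-8 (cross-checked in the test suite).

## β-diversity

Presence/absence only. Pairwise: `β_sor = (b+c)/(2a+b+c)`,
`β_sim = min(b,c)/(a+min(b,c))`, `β_sne = β_sor − β_sim`. Multiple-site
uses the standard summation forms over all site pairs (Σmin, Σmax of
exclusive counts and the pooled-richness deficit ΣSᵢ − S_T). The additive
identity `total = turnover + nestedness` is enforced to 1e-12 by the
result type itself. Reported percentages are rounded half-up to integers
alongside raw proportions.

## Harvest screening

`TimberPolicy` holds per-species minimum felling diameters (default
40 cm where unlisted), a minimum legal harvestable-stem density (default
1 per ha — the customary viability benchmark, deliberately
config-exposed since no statutory number exists), the allowed habitat
set (default `{humid}`), and `require_common`. Eligibility in a habitat
is the conjunction: timber species ∧ Common ∧ allowed habitat ∧
harvestable density ≥ minimum, evaluated on stems outside protected
areas; a species can be eligible in one habitat and not another. All
failed conditions are reported (`NOT_TIMBER`, `RARE_FORM`,
`NOT_GENERALIST` for single-habitat forms, `HABITAT_RESTRICTED`, and
`NO_HARVESTABLE_TREES` or `LOW_DENSITY`). Stems lacking a stem-form
score count toward densities but are excluded from form profiles, which
are conditional on scoring; DBH classes with no scored stems are absent
from the profile rather than zero-filled.

## Synthetic inventory generator

The generator provides parameter-recovery tests for every downstream
stage. It emulates:

* the cluster/plot geometry above, with protected-area membership drawn
  per plot at habitat-specific rates (0.24 / 0.20 / 0.27 for humid /
  semi-arid / rainy);
* a survey of 674 + 180 + 77 = 931 clusters (3724 plots) by default;
* a lognormal regional abundance distribution, log-mean 3.0 and log-sd
  2.0 by default. These were chosen to match the documented marginal
  structure of such surveys: ~10 % singleton species, a few dominants
  with > 1000 records, and ~90 % of species below 1 stem per ha of
  surveyed area;
* 41 % habitat specialists; generalists occupy two habitats, or all
  three with probability 0.45; habitat assignment is weighted by habitat
  extent;
* geographic ranges as contiguous cluster blocks within the species'
  habitat pool — 33 % of species get a narrow block (≤
  `narrow_range_max_units` clusters), the rest a block spanning at least
  ~15 % of the survey. Contiguous blocks produce spatial aggregation
  cheaply; the analysis never uses within-cluster coordinates;
* a truncated Weibull(shape 1.1, scale 15 cm) DBH distribution (support
  ≥ 5 cm): about two-thirds of stems below 20 cm and ~7 % at or above
  40 cm;
* stem forms drawn per DBH class from (SF1, SF2, SF3) probabilities —
  (0.74, 0.17, 0.09), (0.72, 0.19, 0.09), (0.69, 0.07, 0.24) and
  (0.47, 0.20, 0.33) for the 10–20, 20–30, 30–40 and ≥ 40 cm classes —
  the characteristic signature of selective overharvesting of straight
  large stems;
* a 22 % timber fraction with a common 40 cm MFD.

`generate_census` returns the full enumeration plus a truth table
(occupied clusters, habitat set, abundance, rarity form, per-habitat
density, timber attributes) computed from the generator's own placement
bookkeeping — an independent path against which the record-level
pipeline is checked; classification recovery on a census is exact by
construction of matching thresholds, so the test exercises the
aggregation plumbing, not the statistics.

`apply_measurement_protocol` simulates the subplot rule as independent
thinning of small stems with probability `subplot_fraction`, rather than
explicit within-plot geometry: the analysis only ever uses the inclusion
probability, which thinning preserves exactly, making expansion-weighted
densities unbiased for the census (verified by Monte-Carlo, relative
bias < 2 % over 200 replicates).

### What the generator does not emulate

Individuals are placed independently and uniformly within a species'
range block: there is no within-cluster clumping, no distance decay of
similarity beyond the block structure, no climate-driven suitability
surface, and no correlation between a species' abundance and its
protected-area exposure. Passing recovery tests therefore demonstrates
the pipeline's bookkeeping and estimator correctness, not robustness to
the spatial structure of real woodlands.

One structural consequence deserves emphasis: with occupancy-based
geographic range over ~930 clusters, a species must place ≥ ~94
individuals in distinct clusters to classify as wide, so under a
realistic right-skewed abundance distribution most synthetic species are
narrow and the community's rare fraction (~95 %) is far above what field
studies in this system report (~45 %). This is the abundance–occupancy
coupling inherent in the operationalization, not a pipeline defect; real
studies' lower rare fractions imply a coarser geographic unit or a
weaker coupling than uniform placement produces.

## Problem sizes and determinism

The test suite runs censuses of 40–200 species over 36–300 clusters;
`scripts/acceptance.py` runs the full default scale (515 species, 931
clusters, ~75 000 stems) plus 100 thinning replicates for the bias
check. Everything random flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical outputs,
and pipeline reports are written with fixed column order, sorted rows
and a fixed float format to keep re-runs hash-stable.

## Known limitations

* The rarity indices are this package's own forms (see above); compare
  values across index versions with care.
* ACE has no reported SE.
* No taxonomic name resolution, no IUCN category lookup, no GIS or
  climate processing, no volume/allowable-cut or cutting-cycle
  projection, no rarefaction curves, and no abundance-based (Bray-Curtis
  family) β-diversity.
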