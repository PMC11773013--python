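# miombo

Assessment of woody-species rarity, protection status, species richness,
β-diversity and commercial timber availability from nested cluster-plot
forest inventories, with a synthetic inventory generator for testing the
whole pipeline against known ground truth.

The package is written for forest ecologists and inventory analysts
working with national-inventory-style data from seasonally dry African
woodlands (miombo and similar systems): one row per measured stem, nested
cluster → plot → subplot geometry, habitat labels, protected-area flags,
DBH and stem-form scores.

## What it computes

**Rarity forms.** Each species is cross-classified on three binary
criteria — geographic distribution (wide: occupying > 10 % of surveyed
spatial units / narrow: ≤ 10 %), habitat specificity (various: > 1
habitat / single), and local population size (large: abundance > 2 /
small: ≤ 2) — yielding eight categories: *Common* (all three favourable)
and rarity *Forms 1–7*, with Form 7 (narrow, single-habitat, scarce) the
extreme form. Continuous rarity is summarized by a geographical range
index, habitat specificity index and population size index, each in
[0, 1] with higher = rarer, averaged into a rarity index (the exact
functional forms are implementation-defined; see `docs/methods.md`).

**Protection status.** The protection index PI = (occurrences inside
protected areas) / (total occurrences), with occurrences counted as
plot-level presences. PI = 1 → highly protected, PI = 0 → poorly
protected, 0 < PI < 1 → partially protected.

**Richness.** Bias-corrected Chao1,
Ŝ = S_obs + f₁(f₁−1)/(2(f₂+1)), with its standard companion variance,
and the abundance-based coverage estimator (ACE) with rare-group cutoff
10, per habitat.

**β-diversity.** Pairwise and multiple-site Sørensen dissimilarity
partitioned additively into turnover (Simpson dissimilarity) and
nestedness-resultant components: β_sor = β_sim + β_sne.

**Timber availability.** Per species and habitat, the density of stems at
or above the minimum felling diameter (MFD, default 40 cm) outside
protected areas, stem-form profiles (SF1 straight / SF2 wavy / SF3
crooked) by DBH class, and a conjunctive harvest-eligibility rule: legal
timber species ∧ classified Common ∧ allowed habitat ∧ density ≥ legal
minimum — with every failed condition reported as a machine-readable
denial code.

**Expansion factors.** Small stems (DBH 5–10 cm) are censused only in one
subplot covering 25 % of the plot; density computations weight each such
record by 4. Rarity and occurrence statistics use raw counts.

## Worked example

```python
from miombo import CommunityParams, generate_census, apply_measurement_protocol, chao1, community_matrix
from miombo.pipeline import rarity_table, beta_tables
from miombo.rarity import RarityThresholds

params = CommunityParams(n_species=40,
                         clusters_per_habitat={"humid": 25, "semi-arid": 10, "rainy": 5},
                         narrow_range_max_units=4, seed=42)
census, truth = generate_census(params)          # full enumeration + ground truth
field = apply_measurement_protocol(census, seed=43)  # subplot protocol for small stems

rar = rarity_table(field, RarityThresholds(), total_units=params.total_clusters)
print(rar[["species", "form", "pi", "protection"]].head(5).to_string(index=False))
print("rare fraction:", round(rar["is_rare"].mean(), 3))
print(chao1(community_matrix(field, "habitat").abundances("humid")))
print(beta_tables(field)[1].to_string(index=False))
```

prints

```
     species   form       pi protection
Species 0001 Form 6 0.000000     poorly
Species 0002 Form 6 0.250000  partially
Species 0003 Common 0.261905  partially
Species 0005 Form 6 0.500000  partially
Species 0006 Common 0.195122  partially
rare fraction: 0.703
RichnessEstimate(estimator='chao1', estimate=31.5, se=2.2325713874364688)
 n_sites    total  turnover  nestedness
       3 0.734694       0.5    0.234694
```

`Species 0001` was recorded in a single habitat over a narrow cluster
range with abundance > 2 (Form 6) and only outside protected areas
(PI = 0, poorly protected). 70 % of the 40 simulated species show some
form of rarity. The humid assemblage's observed richness extrapolates to
31.5 ± 2.2 species (Chao1), and 73 % of the compositional dissimilarity
across the three habitats is total β-diversity, of which 50 points are
species turnover and 23 nestedness.

The same stages are available from the shell:

```sh
miombo generate --seed 42 --out census.csv --truth truth.csv --apply-protocol
miombo richness --inventory census.csv
miombo beta     --inventory census.csv
miombo rarity   --inventory census.csv
miombo harvest  --inventory census.csv --metadata timber.csv
miombo run      --config config.yaml        # full pipeline + report bundle
```

`miombo run` writes per-habitat richness, β-partition tables, the
per-species rarity/protection table, form and status count summaries,
harvest assessments, and a JSON manifest recording inputs, thresholds and
the seed. Exit code 2 signals a validation error.

## Input formats

Inventory: delimited text (comma or tab autodetected) with columns
`cluster,plot,habitat,protected_area,species,dbh_cm` and optional
`subplot,stem_form`; `protected_area` accepts 0/1/true/false/yes/no.
Species metadata: `species,is_timber,commercial_class,min_felling_dbh_cm`.

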