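"""Commercial timber availability and harvest-eligibility screening.

Logging in the study system is constrained by species (legal timber list),
location (harvest only outside protected areas, and only in habitats where
populations remain viable), and size (a minimum felling diameter, MFD).
This module computes harvestable-stem densities, stem-form profiles by DBH
class, and a conjunctive eligibility rule: a timber species is harvestable
in a habitat only if it is classified Common (geographically and
numerically common habitat generalist), the habitat is on the allowed
list, and its harvestable-stem density meets a legal minimum.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .inventory import (
    SurveyDesign,
    TreeRecord,
    species_key,
    stems_per_ha,
)
from .rarity import SINGLE_HABITAT_FORMS

__all__ = [
    "DENIAL_CODES",
    "DEFAULT_DBH_CLASSES",
    "TimberPolicy",
    "HarvestAssessment",
    "read_species_metadata",
    "harvestable_density",
    "stem_form_profile",
    "harvest_eligibility",
]

DENIAL_CODES = (
    "NOT_TIMBER",
    "RARE_FORM",
    "NOT_GENERALIST",
    "LOW_DENSITY",
    "HABITAT_RESTRICTED",
    "NO_HARVESTABLE_TREES",
)

#: Half-open DBH classes (cm) for stem-form profiling.
DEFAULT_DBH_CLASSES: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, math.inf)


@dataclass
class TimberPolicy:
    """Harvest policy: felling diameters, legal density floor, habitat rule.

    ``min_felling_dbh_cm`` maps species (case-insensitively) to their MFD;
    species absent from the map take ``default_mfd_cm`` (40 cm).
    ``min_harvest_density_per_ha`` is the legal minimum density of
    harvestable stems (default 1 per ha, the customary viability
    benchmark).  ``require_common`` demands the Common rarity category.
    """

    min_felling_dbh_cm: dict[str, float] = field(default_factory=dict)
    default_mfd_cm: float = 40.0
    min_harvest_density_per_ha: float = 1.0
    allowed_habitats: frozenset[str] = frozenset({"humid"})
    require_common: bool = True

    def __post_init__(self) -> None:
        if self.min_harvest_density_per_ha < 0:
            raise ValueError("min_harvest_density_per_ha must be >= 0")
        if not self.allowed_habitats:
            raise ValueError("allowed_habitats must be non-empty")
        self.allowed_habitats = frozenset(self.allowed_habitats)
        self.min_felling_dbh_cm = {
            species_key(k): float(v) for k, v in self.min_felling_dbh_cm.items()
        }

    def mfd_for(self, species: str) -> float:
        return self.min_felling_dbh_cm.get(species_key(species), self.default_mfd_cm)


@dataclass
class HarvestAssessment:
    """Per-species, per-habitat availability and eligibility decision."""

    species: str
    habitat: str
    harvestable_density_per_ha: float
    harvestable_share_of_stems: float
    stem_form_profile: dict[tuple[float, float], tuple[float, float, float]]
    eligible: bool
    reasons: list[str]

    def __post_init__(self) -> None:
        if self.eligible != (not self.reasons):
            raise ValueError("eligible must hold exactly when reasons is empty")
        if not 0 <= self.harvestable_share_of_stems <= 1:
            raise ValueError("harvestable_share_of_stems must lie in [0, 1]")
        for code in self.reasons:
            if code not in DENIAL_CODES:
                raise ValueError(f"unknown denial code {code!r}")


def read_species_metadata(path) -> pd.DataFrame:
    """Read the timber list: species, is_timber, commercial_class, MFD.

    Returns a frame indexed by the canonical species key; ``min_felling_dbh_cm``
    may be empty (NaN) for species with no statutory MFD.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().casefold() for c in df.columns]
    required = {"species", "is_timber"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"species metadata missing column(s): {sorted(missing)}")
    df["species_key"] = df["species"].map(species_key)
    df["is_timber"] = df["is_timber"].map(
        lambda v: str(v).strip().casefold() in {"1", "true", "yes", "y", "t"}
    )
    if "min_felling_dbh_cm" in df.columns:
        df["min_felling_dbh_cm"] = pd.to_numeric(
            df["min_felling_dbh_cm"], errors="coerce"
        )
    return df.set_index("species_key")


def harvestable_density(
    species: str,
    records: Iterable[TreeRecord],
    n_plots: int,
    policy: TimberPolicy,
    design: SurveyDesign | None = None,
) -> float:
    """Density (stems per ha) of harvestable-diameter stems of one species.

    ``records`` must already be restricted to the stratum of interest
    (one habitat, plots outside protected areas); ``n_plots`` is the number
    of surveyed plots in that stratum.
    """
    design = design or SurveyDesign()
    mfd = policy.mfd_for(species)
    key = species_key(species)
    harvestable = [
        r for r in records if species_key(r.species) == key and r.dbh_cm >= mfd
    ]
    return stems_per_ha(harvestable, n_plots, design)


def stem_form_profile(
    records: Iterable[TreeRecord],
    classes: Sequence[float] = DEFAULT_DBH_CLASSES,
) -> dict[tuple[float, float], tuple[float, float, float]]:
    """Relative frequency of (SF1, SF2, SF3) per half-open DBH class.

    Stems without a stem-form score are excluded; classes with no scored
    stems are absent from the result rather than zero-filled.
    """
    edges = list(classes)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("class edges must be strictly increasing")
    bins = list(zip(edges, edges[1:]))
    counts = {b: [0, 0, 0] for b in bins}
    for r in records:
        if r.stem_form is None:
            continue
        for lo, hi in bins:
            if lo <= r.dbh_cm < hi:
                counts[(lo, hi)][int(r.stem_form[2]) - 1] += 1
                break
    profile = {}
    for b, c in counts.items():
        n = sum(c)
        if n > 0:
            profile[b] = (c[0] / n, c[1] / n, c[2] / n)
    return profile


def harvest_eligibility(
    species: str,
    habitat: str,
    is_timber: bool,
    rarity_form: str,
    density_per_ha: float,
    policy: TimberPolicy,
    harvestable_share: float = 0.0,
    profile: dict | None = None,
) -> HarvestAssessment:
    """Conjunctive harvest decision with a complete list of denial reasons.

    Every failed condition is reported, not just the first: the species
    must be a legal timber species, classified Common (when
    ``require_common``), located in an allowed habitat, and meet the legal
    density floor.  Zero harvestable stems is reported as its own reason.
    """
    reasons: list[str] = []
    if not is_timber:
        reasons.append("NOT_TIMBER")
    if policy.require_common and rarity_form != "Common":
        reasons.append("RARE_FORM")
        if rarity_form in SINGLE_HABITAT_FORMS:
            reasons.append("NOT_GENERALIST")
    if habitat not in policy.allowed_habitats:
        reasons.append("HABITAT_RESTRICTED")
    if density_per_ha <= 0:
        reasons.append("NO_HARVESTABLE_TREES")
    elif density_per_ha < policy.min_harvest_density_per_ha:
        reasons.append("LOW_DENSITY")
    return HarvestAssessment(
        species=species,
        habitat=habitat,
        harvestable_density_per_ha=density_per_ha,
        harvestable_share_of_stems=harvestable_share,
        stem_form_profile=profile or {},
        eligible=not reasons,
        reasons=reasons,
    )
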