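"""Rarity forms, rarity indices, and protection status of woody species.

A species is cross-classified on three binary criteria — geographic
distribution (wide / narrow), habitat specificity (various / single
habitat) and local population size (large / small) — giving eight
categories: Common (all three favourable) and rarity Forms 1-7.  The
boundaries follow the printed inequalities exactly: wide means occupying
strictly more than 10 % of the surveyed spatial units, various means more
than one habitat, large means abundance strictly greater than 2.

Continuous rarity is summarized by three [0, 1] indices (higher = rarer):
a geographical range index (GRI), a habitat specificity index (HSI) and a
population size index (PSI), averaged into a rarity index (RI).  The exact
functional forms are implementation-defined (see the methods note): they
preserve the intended semantics and ordering but are not a published
formula, so downstream numbers that depend on them are index-version
specific.

Protection status derives from the protection index (PI), the fraction of
a species' occurrence records that fall inside protected areas: PI = 1 is
highly protected, PI = 0 poorly protected, anything in between partially
protected.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .inventory import SpeciesProfile

__all__ = [
    "RARITY_FORMS",
    "RarityThresholds",
    "RarityAssessment",
    "classify_rabinowitz",
    "maciel_indices",
    "protection_index",
    "protection_status",
    "assess_species",
]

#: (wide, various, large) -> category.  Exactly one combination is Common.
FORM_TABLE: dict[tuple[bool, bool, bool], str] = {
    (True, True, True): "Common",
    (True, True, False): "Form 1",
    (True, False, True): "Form 2",
    (True, False, False): "Form 3",
    (False, True, True): "Form 4",
    (False, True, False): "Form 5",
    (False, False, True): "Form 6",
    (False, False, False): "Form 7",
}

RARITY_FORMS: tuple[str, ...] = tuple(FORM_TABLE.values())

#: Categories whose habitat-specificity criterion is "single habitat".
SINGLE_HABITAT_FORMS = frozenset({"Form 2", "Form 3", "Form 6", "Form 7"})


@dataclass(frozen=True)
class RarityThresholds:
    """Classification boundaries for the three binary rarity criteria.

    ``wide_range_min_prop`` is applied strictly: a species is wide-ranging
    only if its occupied proportion exceeds it, so exactly 10 % occupancy
    is narrow.  ``abundance_scope`` selects whether the population-size
    criterion looks at the species' maximum abundance in any single habitat
    ("somewhere large", the default) or its total abundance.
    """

    wide_range_min_prop: float = 0.10
    habitat_various_min: int = 2
    abundance_large_min: int = 3
    abundance_scope: str = "max_per_habitat"

    def __post_init__(self) -> None:
        if not 0 < self.wide_range_min_prop < 1:
            raise ValueError("wide_range_min_prop must be in (0, 1)")
        if self.habitat_various_min < 1 or self.abundance_large_min < 1:
            raise ValueError("criterion minima must be positive")
        if self.abundance_scope not in ("max_per_habitat", "total"):
            raise ValueError("abundance_scope must be 'max_per_habitat' or 'total'")


@dataclass
class RarityAssessment:
    """Full rarity and protection assessment for one species."""

    species: str
    form: str
    is_rare: bool
    indices: dict[str, float]
    pi: float
    protection: str

    def __post_init__(self) -> None:
        if self.is_rare != (self.form != "Common"):
            raise ValueError("is_rare inconsistent with form")


def classify_rabinowitz(
    profile: SpeciesProfile, thresholds: RarityThresholds | None = None
) -> str:
    """Map a species profile to Common or one of the seven rarity forms."""
    thresholds = thresholds or RarityThresholds()
    if profile.total_units <= 0 or profile.total_abundance <= 0:
        raise ValueError("profile must cover at least one unit and one record")
    wide = profile.occupancy_proportion > thresholds.wide_range_min_prop
    various = profile.n_habitats >= thresholds.habitat_various_min
    if thresholds.abundance_scope == "max_per_habitat":
        abundance = profile.max_habitat_abundance
    else:
        abundance = profile.total_abundance
    large = abundance >= thresholds.abundance_large_min
    return FORM_TABLE[(wide, various, large)]


def maciel_indices(
    profile: SpeciesProfile,
    total_units: int,
    n_habitats: int,
    max_abundance_overall: int,
) -> dict[str, float]:
    """Continuous rarity indices, each in [0, 1], higher = rarer.

    GRI is the complement of proportional occupancy; HSI the complement of
    the habitat breadth scaled over the study's habitat count (1 by
    convention in a one-habitat region); PSI the complement of
    log-abundance scaled against the most abundant species:

        gri = 1 - occupied / total
        hsi = 1 - (h - 1) / (H - 1)
        psi = 1 - log(1 + n) / log(1 + n_max)
        ri  = (gri + hsi + psi) / 3
    """
    if max_abundance_overall <= 0:
        raise ValueError("max_abundance_overall must be positive")
    if total_units <= 0:
        raise ValueError("total_units must be positive")
    gri = 1.0 - profile.occupied_units / total_units
    h = profile.n_habitats
    hsi = 1.0 if n_habitats <= 1 else 1.0 - (h - 1) / (n_habitats - 1)
    n = profile.total_abundance
    psi = 1.0 - math.log1p(n) / math.log1p(max_abundance_overall)
    ri = (gri + hsi + psi) / 3.0
    return {"gri": gri, "hsi": hsi, "psi": psi, "ri": ri}


def protection_index(occ_in_pa: int, occ_total: int) -> float:
    """Fraction of occurrence records inside protected areas."""
    if occ_total < 1:
        raise ValueError("occ_total must be >= 1")
    if not 0 <= occ_in_pa <= occ_total:
        raise ValueError("occ_in_pa must be between 0 and occ_total")
    return occ_in_pa / occ_total


def protection_status(pi: float) -> str:
    """``highly`` (PI = 1), ``poorly`` (PI = 0) or ``partially`` (0 < PI < 1)."""
    if not 0 <= pi <= 1:
        raise ValueError("PI must lie in [0, 1]")
    if pi == 1:
        return "highly"
    if pi == 0:
        return "poorly"
    return "partially"


def assess_species(
    profile: SpeciesProfile,
    thresholds: RarityThresholds,
    n_habitats: int,
    max_abundance_overall: int,
) -> RarityAssessment:
    """Combine form classification, rarity indices and protection status."""
    form = classify_rabinowitz(profile, thresholds)
    indices = maciel_indices(
        profile, profile.total_units, n_habitats, max_abundance_overall
    )
    pi = protection_index(profile.occurrences_in_pa, profile.occurrences_total)
    return RarityAssessment(
        species=profile.species,
        form=form,
        is_rare=form != "Common",
        indices=indices,
        pi=pi,
        protection=protection_status(pi),
    )
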