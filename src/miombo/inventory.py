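"""Data model and I/O for nested cluster-plot forest inventories.

The sampling unit is a 1 ha square cluster holding four 0.1 ha (50 x 20 m)
rectangular plots at its corners.  Every stem with DBH >= 10 cm is measured
in the full plot; stems in the small-DBH range (default 5-10 cm) are
censused only in one 25 x 10 m subplot, i.e. a known fraction of the plot
area.  Densities therefore need per-record expansion factors, while
rarity and occurrence statistics use raw record counts.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_HABITATS",
    "STEM_FORMS",
    "TreeRecord",
    "SurveyDesign",
    "SpeciesProfile",
    "CommunityMatrix",
    "RowIssue",
    "InventoryReadResult",
    "normalize_species_name",
    "species_key",
    "read_inventory",
    "write_inventory",
    "records_to_frame",
    "expansion_factor",
    "stems_per_ha",
    "build_profiles",
    "community_matrix",
]

DEFAULT_HABITATS: tuple[str, ...] = ("humid", "semi-arid", "rainy")

#: Stem-form scores for sawmilling suitability: SF1 straight (ideal),
#: SF2 wavy (partially usable), SF3 crooked (unsuitable).
STEM_FORMS: tuple[str, ...] = ("SF1", "SF2", "SF3")

_WS = re.compile(r"\s+")

_TRUE_STRINGS = {"1", "true", "yes", "y", "t"}
_FALSE_STRINGS = {"0", "false", "no", "n", "f"}

REQUIRED_COLUMNS = ("cluster", "plot", "habitat", "protected_area", "species", "dbh_cm")
OPTIONAL_COLUMNS = ("subplot", "stem_form")


def normalize_species_name(name: str) -> str:
    """Trim and collapse internal whitespace; no fuzzy matching."""
    return _WS.sub(" ", str(name).strip())


def species_key(name: str) -> str:
    """Casefolded canonical key used for deterministic joins."""
    return normalize_species_name(name).casefold()


class SchemaError(ValueError):
    """The input table is missing a mandatory column."""


@dataclass(frozen=True)
class SurveyDesign:
    """Geometry of the nested plot/subplot measurement protocol.

    Parameters
    ----------
    plot_area_ha:
        Area of one rectangular plot in hectares (default 0.1 ha = 50 x 20 m).
    subplot_fraction:
        Fraction of the plot covered by the single subplot in which
        small-DBH stems are censused (default 0.25, a 25 x 10 m subplot).
    small_tree_range_cm:
        Half-open DBH interval ``[lo, hi)`` measured only in the subplot.
    habitats:
        Registered habitat labels; records with other labels are rejected.
    """

    plot_area_ha: float = 0.1
    subplot_fraction: float = 0.25
    small_tree_range_cm: tuple[float, float] = (5.0, 10.0)
    habitats: tuple[str, ...] = DEFAULT_HABITATS

    def __post_init__(self) -> None:
        if not self.plot_area_ha > 0:
            raise ValueError("plot_area_ha must be positive")
        if not 0 < self.subplot_fraction <= 1:
            raise ValueError("subplot_fraction must be in (0, 1]")
        lo, hi = self.small_tree_range_cm
        if not (0 <= lo < hi):
            raise ValueError("small_tree_range_cm must satisfy 0 <= lo < hi")
        if not self.habitats:
            raise ValueError("habitats must be non-empty")

    @property
    def cluster_area_ha(self) -> float:
        return 4 * self.plot_area_ha


@dataclass(frozen=True)
class TreeRecord:
    """One measured stem with its full location context.

    ``stem_form`` is scored only for stems with DBH >= 10 cm; field data may
    lack the score, in which case it is ``None``.
    """

    cluster_id: str
    plot_id: str
    habitat: str
    in_protected_area: bool
    species: str
    dbh_cm: float
    stem_form: str | None = None
    subplot_id: str | None = None

    def __post_init__(self) -> None:
        if not self.species or not str(self.species).strip():
            raise ValueError("species must be non-empty")
        if not self.dbh_cm >= 5:
            raise ValueError(f"dbh_cm must be >= 5, got {self.dbh_cm}")
        if self.stem_form is not None:
            if self.stem_form not in STEM_FORMS:
                raise ValueError(f"unknown stem_form {self.stem_form!r}")
            if self.dbh_cm < 10:
                raise ValueError("stem_form is scored only for DBH >= 10 cm")

    @property
    def plot_key(self) -> tuple[str, str]:
        return (self.cluster_id, self.plot_id)


@dataclass
class SpeciesProfile:
    """Per-species aggregate feeding the rarity and protection classifiers.

    Occurrences are plot-level presence records: a species seen in a plot
    counts once regardless of stem count.  ``occupied_units`` counts spatial
    units (clusters by default) holding at least one record.
    """

    species: str
    abundance_by_habitat: dict[str, int]
    occupied_units: int
    total_units: int
    occurrences_in_pa: int
    occurrences_total: int

    def __post_init__(self) -> None:
        if self.occurrences_in_pa > self.occurrences_total:
            raise ValueError("occurrences_in_pa exceeds occurrences_total")
        if self.occupied_units > self.total_units:
            raise ValueError("occupied_units exceeds total_units")

    @property
    def total_abundance(self) -> int:
        return sum(self.abundance_by_habitat.values())

    @property
    def n_habitats(self) -> int:
        return sum(1 for v in self.abundance_by_habitat.values() if v > 0)

    @property
    def max_habitat_abundance(self) -> int:
        return max(self.abundance_by_habitat.values(), default=0)

    @property
    def occupancy_proportion(self) -> float:
        return self.occupied_units / self.total_units


@dataclass
class CommunityMatrix:
    """Sites x species table of abundances or presences."""

    sites: list[str]
    species: list[str]
    values: np.ndarray  # shape (n_sites, n_species)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.sites), len(self.species)):
            raise ValueError("matrix shape inconsistent with labels")
        if (self.values < 0).any():
            raise ValueError("community matrix values must be non-negative")

    def presence(self) -> "CommunityMatrix":
        """Indicator (0/1) version of the matrix."""
        return CommunityMatrix(
            list(self.sites), list(self.species), (self.values > 0).astype(int)
        )

    def site_set(self, site: str) -> frozenset[str]:
        i = self.sites.index(site)
        row = self.values[i]
        return frozenset(s for s, v in zip(self.species, row) if v > 0)

    def abundances(self, site: str) -> np.ndarray:
        """Positive per-species abundances at one site (richness input)."""
        row = self.values[self.sites.index(site)]
        return row[row > 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sites, columns=self.species)


@dataclass(frozen=True)
class RowIssue:
    row: int  # 1-based data row number (header excluded)
    field: str
    message: str


@dataclass
class InventoryReadResult:
    records: list[TreeRecord]
    rejected: list[RowIssue]
    warnings: list[str]


def _parse_bool(raw: str) -> bool:
    s = str(raw).strip().casefold()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise ValueError(f"cannot interpret {raw!r} as a protected-area flag")


def read_inventory(path: str | Path, design: SurveyDesign | None = None) -> InventoryReadResult:
    """Parse a delimited inventory file into validated :class:`TreeRecord` s.

    The delimiter (comma or tab) is autodetected.  Rows violating the data
    model (DBH below the census threshold, unknown habitat, missing species)
    are rejected individually and reported with their 1-based row number;
    stems >= 10 cm with no stem-form score are accepted with a warning.
    """
    design = design or SurveyDesign()
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df.columns = [str(c).strip().casefold() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[TreeRecord] = []
    rejected: list[RowIssue] = []
    n_unscored = 0
    lo = design.small_tree_range_cm[0]
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        r = dict(zip(df.columns, row))
        try:
            dbh = float(r["dbh_cm"])
        except ValueError:
            rejected.append(RowIssue(idx, "dbh_cm", f"non-numeric DBH {r['dbh_cm']!r}"))
            continue
        if dbh < lo:
            rejected.append(
                RowIssue(idx, "dbh_cm", f"DBH {dbh} below census threshold {lo} cm")
            )
            continue
        habitat = str(r["habitat"]).strip()
        if habitat not in design.habitats:
            rejected.append(RowIssue(idx, "habitat", f"unknown habitat label {habitat!r}"))
            continue
        try:
            in_pa = _parse_bool(r["protected_area"])
        except ValueError as exc:
            rejected.append(RowIssue(idx, "protected_area", str(exc)))
            continue
        form = str(r.get("stem_form", "")).strip() or None
        subplot = str(r.get("subplot", "")).strip() or None
        try:
            rec = TreeRecord(
                cluster_id=str(r["cluster"]).strip(),
                plot_id=str(r["plot"]).strip(),
                habitat=habitat,
                in_protected_area=in_pa,
                species=normalize_species_name(r["species"]),
                dbh_cm=dbh,
                stem_form=form,
                subplot_id=subplot,
            )
        except ValueError as exc:
            rejected.append(RowIssue(idx, "record", str(exc)))
            continue
        if rec.dbh_cm >= 10 and rec.stem_form is None:
            n_unscored += 1
        records.append(rec)

    warnings: list[str] = []
    if n_unscored:
        warnings.append(
            f"{n_unscored} stem(s) with DBH >= 10 cm lack a stem-form score"
        )
    return InventoryReadResult(records, rejected, warnings)


def records_to_frame(records: Iterable[TreeRecord]) -> pd.DataFrame:
    rows = [
        {
            "cluster": r.cluster_id,
            "plot": r.plot_id,
            "subplot": r.subplot_id or "",
            "habitat": r.habitat,
            "protected_area": int(r.in_protected_area),
            "species": r.species,
            "dbh_cm": r.dbh_cm,
            "stem_form": r.stem_form or "",
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster", "plot", "subplot", "habitat",
            "protected_area", "species", "dbh_cm", "stem_form",
        ],
    )


def write_inventory(records: Iterable[TreeRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def expansion_factor(record: TreeRecord, design: SurveyDesign) -> float:
    """Plot-scale weight of one record.

    Small-DBH stems are censused only in a subplot covering
    ``subplot_fraction`` of the plot, so each such record represents
    ``1 / subplot_fraction`` stems at plot scale; all other stems weigh 1.
    """
    lo, hi = design.small_tree_range_cm
    if record.dbh_cm < lo:
        raise ValueError(f"DBH {record.dbh_cm} below census threshold {lo} cm")
    if lo <= record.dbh_cm < hi:
        return 1.0 / design.subplot_fraction
    return 1.0


def stems_per_ha(
    records: Iterable[TreeRecord], n_plots: int, design: SurveyDesign | None = None
) -> float:
    """Expansion-weighted stem density over ``n_plots`` surveyed plots."""
    design = design or SurveyDesign()
    if n_plots <= 0:
        raise ValueError("n_plots must be positive")
    total = sum(expansion_factor(r, design) for r in records)
    return total / (n_plots * design.plot_area_ha)


def build_profiles(
    records: Sequence[TreeRecord],
    unit: str = "cluster",
    total_units: int | None = None,
) -> dict[str, SpeciesProfile]:
    """Aggregate records into per-species profiles.

    ``unit`` selects the occupancy unit for the geographic-range criterion:
    ``"cluster"`` (spatially independent sampling locations, the default) or
    ``"plot"``.  Counts are raw (no expansion weighting): rarity thresholds
    refer to recorded individuals.  ``total_units`` defaults to the number
    of distinct units present in ``records``.
    """
    if unit not in ("cluster", "plot"):
        raise ValueError("unit must be 'cluster' or 'plot'")

    def unit_key(r: TreeRecord):
        return r.cluster_id if unit == "cluster" else r.plot_key

    all_units = {unit_key(r) for r in records}
    if total_units is None:
        total_units = len(all_units)
    elif total_units < len(all_units):
        raise ValueError("total_units smaller than units present in records")

    by_species: dict[str, dict] = {}
    for r in records:
        agg = by_species.setdefault(
            r.species,
            {"abund": {}, "units": set(), "plots": set(), "pa_plots": set()},
        )
        agg["abund"][r.habitat] = agg["abund"].get(r.habitat, 0) + 1
        agg["units"].add(unit_key(r))
        agg["plots"].add(r.plot_key)
        if r.in_protected_area:
            agg["pa_plots"].add(r.plot_key)

    profiles: dict[str, SpeciesProfile] = {}
    for sp in sorted(by_species):
        agg = by_species[sp]
        profiles[sp] = SpeciesProfile(
            species=sp,
            abundance_by_habitat=dict(sorted(agg["abund"].items())),
            occupied_units=len(agg["units"]),
            total_units=total_units,
            occurrences_in_pa=len(agg["pa_plots"]),
            occurrences_total=len(agg["plots"]),
        )
    return profiles


def community_matrix(
    records: Sequence[TreeRecord],
    sites: str | Callable[[TreeRecord], str] = "habitat",
) -> CommunityMatrix:
    """Build a sites x species abundance matrix.

    ``sites`` is a partition rule: ``"habitat"``, ``"cluster"``,
    ``"habitat_pa"`` (habitat crossed with protected-area membership), or a
    callable mapping each record to a site label.  A rule returning a
    false-y label raises.
    """
    if callable(sites):
        rule = sites
    elif sites == "habitat":
        rule = lambda r: r.habitat
    elif sites == "cluster":
        rule = lambda r: r.cluster_id
    elif sites == "habitat_pa":
        rule = lambda r: f"{r.habitat}:{'PA' if r.in_protected_area else 'outside'}"
    else:
        raise ValueError(f"unknown partition rule {sites!r}")

    counts: dict[tuple[str, str], int] = {}
    site_labels: set[str] = set()
    species_labels: set[str] = set()
    for r in records:
        site = rule(r)
        if not site:
            raise ValueError(f"record {r} matched no site")
        counts[(site, r.species)] = counts.get((site, r.species), 0) + 1
        site_labels.add(site)
        species_labels.add(r.species)

    sites_sorted = sorted(site_labels)
    species_sorted = sorted(species_labels)
    mat = np.zeros((len(sites_sorted), len(species_sorted)), dtype=int)
    si = {s: i for i, s in enumerate(sites_sorted)}
    pj = {s: j for j, s in enumerate(species_sorted)}
    for (site, sp), n in counts.items():
        mat[si[site], pj[sp]] = n
    return CommunityMatrix(sites_sorted, species_sorted, mat)
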