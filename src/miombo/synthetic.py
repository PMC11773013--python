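"""Synthetic cluster-plot inventories with known ground truth.

The generator emulates the statistical structure of a national woodland
inventory over three climatic ecoregions (humid, semi-arid, rainy): 1 ha
clusters of four 0.1 ha plots, protected-area membership per plot, a
strongly right-skewed lognormal species-abundance distribution (few
dominant species, many singletons and doubletons), a mix of habitat
specialists and generalists, restricted and widespread geographic ranges
realized as contiguous cluster blocks, a small-stem-dominated truncated
Weibull DBH distribution, and DBH-class-dependent stem-form frequencies.

``generate_census`` returns a full census (every stem >= 5 cm enumerated
over whole plots) together with a truth table computed directly from the
generator's own placement bookkeeping — an independent path against which
the record-level aggregation pipeline can be checked.
``apply_measurement_protocol`` then simulates the field protocol in which
small stems are censused only in one subplot, by independent thinning with
the subplot's known area fraction as inclusion probability.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inventory import SurveyDesign, TreeRecord
from .rarity import FORM_TABLE, RarityThresholds

__all__ = ["CommunityParams", "generate_census", "apply_measurement_protocol"]


def _default_clusters() -> dict[str, int]:
    # ~3725 plots split ~72/19/8 % across humid / semi-arid / rainy
    return {"humid": 674, "semi-arid": 180, "rainy": 77}


def _default_pa_fraction() -> dict[str, float]:
    return {"humid": 0.24, "semi-arid": 0.20, "rainy": 0.27}


def _default_stem_form_probs() -> dict[tuple[float, float], tuple[float, float, float]]:
    # straight / wavy / crooked shares shift toward crooked stems in the
    # large classes (overharvesting residue of straight large stems)
    return {
        (10.0, 20.0): (0.74, 0.17, 0.09),
        (20.0, 30.0): (0.72, 0.19, 0.09),
        (30.0, 40.0): (0.69, 0.07, 0.24),
        (40.0, math.inf): (0.47, 0.20, 0.33),
    }


@dataclass
class CommunityParams:
    """Ground-truth community and survey parameters.

    Defaults describe a survey of ~930 clusters (~3725 plots) across three
    ecoregions with ~515 woody species and a heavy-tailed lognormal
    abundance distribution (log-mean 3.0, log-sd 2.0): roughly 10 % of
    species are singletons, a few dominants exceed 1000 records, and ~90 %
    of species fall below 1 stem per ha of surveyed area.  41 % of species
    are habitat specialists and 33 % geographically restricted.  The
    truncated Weibull(1.1, 15) DBH distribution puts about two-thirds of
    stems below 20 cm and ~7 % at or above the 40 cm felling diameter.
    """

    n_species: int = 515
    habitats: tuple[str, ...] = ("humid", "semi-arid", "rainy")
    clusters_per_habitat: dict[str, int] = field(default_factory=_default_clusters)
    plots_per_cluster: int = 4
    pa_fraction: dict[str, float] = field(default_factory=_default_pa_fraction)
    abundance_log_mean: float = 3.0
    abundance_log_sd: float = 2.0
    specialist_fraction: float = 0.41
    generalist_full_fraction: float = 0.45  # generalists present in all habitats
    narrow_range_fraction: float = 0.33
    narrow_range_max_units: int = 20
    dbh_weibull_shape: float = 1.1
    dbh_weibull_scale: float = 15.0
    stem_form_probs: dict[tuple[float, float], tuple[float, float, float]] = field(
        default_factory=_default_stem_form_probs
    )
    timber_fraction: float = 0.22
    mfd_cm: float = 40.0
    plot_area_ha: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be positive")
        for frac in (
            self.specialist_fraction,
            self.generalist_full_fraction,
            self.narrow_range_fraction,
            self.timber_fraction,
            *self.pa_fraction.values(),
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for probs in self.stem_form_probs.values():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("stem-form probabilities must sum to 1")
        n_clusters = sum(self.clusters_per_habitat.values())
        if self.narrow_range_max_units > n_clusters:
            raise ValueError(
                "narrow_range_max_units exceeds the number of clusters surveyed"
            )
        if self.narrow_range_max_units < 1 or self.plots_per_cluster < 1:
            raise ValueError("counts must be positive")

    @property
    def total_clusters(self) -> int:
        return sum(self.clusters_per_habitat[h] for h in self.habitats)


def _truncated_weibull(rng: np.random.Generator, shape: float, scale: float,
                       lo: float, size: int) -> np.ndarray:
    """Inverse-CDF sample of Weibull(shape, scale) conditional on X >= lo."""
    F_lo = 1.0 - math.exp(-((lo / scale) ** shape))
    u = rng.random(size)
    return scale * (-np.log1p(-(F_lo + u * (1.0 - F_lo)))) ** (1.0 / shape)


def _sample_stem_form(rng: np.random.Generator, dbh: float,
                      probs: dict) -> str | None:
    if dbh < 10:
        return None
    for (lo, hi), p in probs.items():
        if lo <= dbh < hi:
            return ("SF1", "SF2", "SF3")[rng.choice(3, p=p)]
    return None


def generate_census(
    params: CommunityParams,
    thresholds: RarityThresholds | None = None,
) -> tuple[list[TreeRecord], pd.DataFrame]:
    """Generate a full census and its truth table.

    Deterministic under a fixed ``params.seed``.  The truth table holds,
    per species: realized occupied clusters (``true_range_units``),
    realized habitat set, total abundance, the rarity category obtained by
    applying ``thresholds`` to the census quantities, true per-habitat
    densities (stems per ha of surveyed plot area), and timber attributes.
    """
    thresholds = thresholds or RarityThresholds()
    rng = np.random.default_rng(params.seed)
    habitats = list(params.habitats)

    # cluster layout: contiguous ids per habitat define the range ordering
    clusters: dict[str, list[str]] = {}
    cluster_habitat: dict[str, str] = {}
    for h in habitats:
        ids = [f"{h}-C{i + 1:04d}" for i in range(params.clusters_per_habitat[h])]
        clusters[h] = ids
        for cid in ids:
            cluster_habitat[cid] = h

    # protected-area membership is a plot attribute
    pa_flag: dict[tuple[str, str], bool] = {}
    for h in habitats:
        for cid in clusters[h]:
            for p in range(params.plots_per_cluster):
                pa_flag[(cid, f"P{p + 1}")] = bool(rng.random() < params.pa_fraction[h])

    weights = np.array([len(clusters[h]) for h in habitats], dtype=float)
    weights /= weights.sum()

    records: list[TreeRecord] = []
    truth_rows: list[dict] = []
    for s in range(params.n_species):
        name = f"Species {s + 1:04d}"
        # habitat pool: specialists get one habitat, generalists two or all
        if rng.random() < params.specialist_fraction:
            k = 1
        elif rng.random() < params.generalist_full_fraction:
            k = min(3, len(habitats))
        else:
            k = min(2, len(habitats))
        pool_habitats = list(
            rng.choice(habitats, size=k, replace=False, p=weights)
        )
        pool = [cid for h in pool_habitats for cid in clusters[h]]

        # geographic range: contiguous block of clusters within the pool
        if rng.random() < params.narrow_range_fraction:
            span = int(rng.integers(1, min(params.narrow_range_max_units, len(pool)) + 1))
        else:
            lo_span = min(len(pool), max(2, math.ceil(0.15 * params.total_clusters)))
            span = int(rng.integers(lo_span, len(pool) + 1))
        start = int(rng.integers(0, len(pool) - span + 1))
        range_clusters = pool[start:start + span]

        n = max(1, int(round(rng.lognormal(params.abundance_log_mean,
                                           params.abundance_log_sd))))
        placed = rng.choice(len(range_clusters), size=n)
        plot_idx = rng.integers(0, params.plots_per_cluster, size=n)
        dbh = np.round(
            _truncated_weibull(rng, params.dbh_weibull_shape,
                               params.dbh_weibull_scale, 5.0, n), 1)
        is_timber = bool(rng.random() < params.timber_fraction)

        occupied: set[str] = set()
        abundance_by_habitat: dict[str, int] = {h: 0 for h in habitats}
        for i in range(n):
            cid = range_clusters[int(placed[i])]
            h = cluster_habitat[cid]
            pid = f"P{int(plot_idx[i]) + 1}"
            records.append(
                TreeRecord(
                    cluster_id=cid,
                    plot_id=pid,
                    habitat=h,
                    in_protected_area=pa_flag[(cid, pid)],
                    species=name,
                    dbh_cm=float(max(dbh[i], 5.0)),
                    stem_form=_sample_stem_form(rng, dbh[i], params.stem_form_probs),
                )
            )
            occupied.add(cid)
            abundance_by_habitat[h] += 1

        # truth computed from placement bookkeeping, not from the records
        occ_habitats = sorted(h for h in habitats if abundance_by_habitat[h] > 0)
        wide = len(occupied) / params.total_clusters > thresholds.wide_range_min_prop
        various = len(occ_habitats) >= thresholds.habitat_various_min
        if thresholds.abundance_scope == "max_per_habitat":
            ab = max(abundance_by_habitat.values())
        else:
            ab = n
        large = ab >= thresholds.abundance_large_min
        row = {
            "species": name,
            "true_range_units": len(occupied),
            "true_habitats": ";".join(occ_habitats),
            "true_total_abundance": n,
            "true_rarity_form": FORM_TABLE[(wide, various, large)],
            "is_timber": is_timber,
            "mfd_cm": params.mfd_cm,
        }
        for h in habitats:
            area = params.clusters_per_habitat[h] * params.plots_per_cluster * params.plot_area_ha
            row[f"true_density_per_ha_{h}"] = abundance_by_habitat[h] / area
        truth_rows.append(row)

    truth = pd.DataFrame(truth_rows).set_index("species", drop=False)
    return records, truth


def apply_measurement_protocol(
    census: list[TreeRecord],
    design: SurveyDesign | None = None,
    seed: int = 0,
) -> list[TreeRecord]:
    """Simulate subplot-only measurement of small stems by thinning.

    Stems in the small-DBH range are retained independently with
    probability ``design.subplot_fraction`` (the subplot's area share) and
    flagged as subplot records; all larger stems are kept unchanged.  The
    known inclusion probability is exactly what the expansion factors in
    density estimation undo, so thinned densities are unbiased for the
    census densities.
    """
    design = design or SurveyDesign()
    rng = np.random.default_rng(seed)
    lo, hi = design.small_tree_range_cm
    out: list[TreeRecord] = []
    for r in census:
        if lo <= r.dbh_cm < hi:
            if rng.random() < design.subplot_fraction:
                out.append(
                    TreeRecord(
                        cluster_id=r.cluster_id,
                        plot_id=r.plot_id,
                        habitat=r.habitat,
                        in_protected_area=r.in_protected_area,
                        species=r.species,
                        dbh_cm=r.dbh_cm,
                        stem_form=r.stem_form,
                        subplot_id="A",
                    )
                )
        else:
            out.append(r)
    return out
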