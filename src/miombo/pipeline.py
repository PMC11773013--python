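"""End-to-end assessment pipeline and report tables.

Stage order: read inventory -> species profiles -> richness per habitat ->
beta-diversity partition -> per-species rarity/protection -> commercial
harvest screening.  All outputs are delimited text plus a JSON run
manifest; given the same config and seed the outputs are byte-identical.
"""
from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .beta import multisite_beta, pairwise_beta
from .commercial import (
    DEFAULT_DBH_CLASSES,
    TimberPolicy,
    harvest_eligibility,
    harvestable_density,
    read_species_metadata,
    stem_form_profile,
)
from .inventory import (
    InventoryReadResult,
    SurveyDesign,
    TreeRecord,
    build_profiles,
    community_matrix,
    read_inventory,
    species_key,
)
from .rarity import RarityThresholds, assess_species
from .richness import ace, chao1

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending context."""


@dataclass
class RunConfig:
    inventory: str | Path
    outdir: str | Path
    species_metadata: str | Path | None = None
    unit: str = "plot"  # occurrence unit for the protection index
    range_unit: str = "cluster"  # occupancy unit for the geographic criterion
    design: SurveyDesign = field(default_factory=SurveyDesign)
    thresholds: RarityThresholds = field(default_factory=RarityThresholds)
    policy: TimberPolicy = field(default_factory=TimberPolicy)
    #: surveyed-unit count for the geographic-range denominator; None derives
    #: it from the units present in the inventory (understates the survey if
    #: some surveyed units held no stems)
    total_units: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design_raw = raw.get("design", {})
        if "small_tree_range_cm" in design_raw:
            design_raw["small_tree_range_cm"] = tuple(design_raw["small_tree_range_cm"])
        if "habitats" in design_raw:
            design_raw["habitats"] = tuple(design_raw["habitats"])
        policy_raw = dict(raw.get("policy", {}))
        if "allowed_habitats" in policy_raw:
            policy_raw["allowed_habitats"] = frozenset(policy_raw["allowed_habitats"])
        return cls(
            inventory=raw["inventory"],
            outdir=raw.get("outdir", "out"),
            species_metadata=raw.get("species_metadata"),
            unit=raw.get("unit", "plot"),
            range_unit=raw.get("range_unit", "cluster"),
            design=SurveyDesign(**design_raw),
            thresholds=RarityThresholds(**raw.get("thresholds", {})),
            policy=TimberPolicy(**policy_raw),
            total_units=raw.get("total_units"),
            seed=int(raw.get("seed", 0)),
        )


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def rarity_table(
    records: Sequence[TreeRecord],
    thresholds: RarityThresholds,
    range_unit: str = "cluster",
    design: SurveyDesign | None = None,
    total_units: int | None = None,
) -> pd.DataFrame:
    """Per-species rarity, indices, and protection status table.

    ``total_units`` is the geographic-range denominator (all surveyed
    units); it defaults to the number of distinct units present in
    ``records``, which understates the survey if some units held no stems.
    """
    design = design or SurveyDesign()
    profiles = build_profiles(records, unit=range_unit, total_units=total_units)
    if not profiles:
        raise PipelineError("rarity: no species in the inventory")
    n_habitats = len({r.habitat for r in records})
    max_ab = max(p.total_abundance for p in profiles.values())
    rows = []
    for sp in sorted(profiles):
        a = assess_species(profiles[sp], thresholds, n_habitats, max_ab)
        rows.append(
            {
                "species": sp,
                "form": a.form,
                "is_rare": a.is_rare,
                "gri": a.indices["gri"],
                "hsi": a.indices["hsi"],
                "psi": a.indices["psi"],
                "ri": a.indices["ri"],
                "pi": a.pi,
                "protection": a.protection,
                "total_abundance": profiles[sp].total_abundance,
                "n_habitats": profiles[sp].n_habitats,
                "occupied_units": profiles[sp].occupied_units,
            }
        )
    return pd.DataFrame(rows)


def richness_table(records: Sequence[TreeRecord]) -> pd.DataFrame:
    """Observed richness, Chao1 and ACE per habitat and overall."""
    cm = community_matrix(records, "habitat")
    rows = []
    groups = [(site, cm.abundances(site)) for site in cm.sites]
    pooled = build_profiles(records)
    groups.append(("all", pd.Series([p.total_abundance for p in pooled.values()]).to_numpy()))
    for label, ab in groups:
        c = chao1(ab)
        a = ace(ab)
        rows.append(
            {
                "site": label,
                "n_individuals": int(ab.sum()),
                "s_obs": int(len(ab)),
                "chao1": c.estimate,
                "chao1_se": c.se,
                "ace": a.estimate,
            }
        )
    return pd.DataFrame(rows)


def beta_tables(records: Sequence[TreeRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise (long format) and multiple-site beta partitions by habitat."""
    cm = community_matrix(records, "habitat").presence()
    rows = []
    for i, si in enumerate(cm.sites):
        for sj in cm.sites[i + 1:]:
            b = pairwise_beta(cm.site_set(si), cm.site_set(sj))
            rows.append(
                {
                    "site_i": si,
                    "site_j": sj,
                    "total": b.total,
                    "turnover": b.turnover,
                    "nestedness": b.nestedness,
                }
            )
    pair = pd.DataFrame(rows)
    if len(cm.sites) >= 2:
        m = multisite_beta(cm)
        multi = pd.DataFrame(
            [{"n_sites": len(cm.sites), "total": m.total,
              "turnover": m.turnover, "nestedness": m.nestedness}]
        )
    else:
        multi = pd.DataFrame(columns=["n_sites", "total", "turnover", "nestedness"])
    return pair, multi


def harvest_table(
    records: Sequence[TreeRecord],
    rarity: pd.DataFrame,
    policy: TimberPolicy,
    design: SurveyDesign,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-timber-species, per-habitat harvest assessment (outside PAs)."""
    form_by_species = dict(zip(rarity["species"], rarity["form"]))
    habitats = sorted({r.habitat for r in records})
    rows = []
    for habitat in habitats:
        stratum = [r for r in records
                   if r.habitat == habitat and not r.in_protected_area]
        n_plots = len({r.plot_key for r in stratum})
        if n_plots == 0:
            continue
        all_stems = len(stratum)
        species_here = sorted({r.species for r in stratum})
        for sp in species_here:
            key = species_key(sp)
            if metadata is not None and key in metadata.index:
                meta = metadata.loc[key]
                is_timber = bool(meta["is_timber"])
            else:
                is_timber = metadata is None  # no list: screen every species
            density = harvestable_density(sp, stratum, n_plots, policy, design)
            mfd = policy.mfd_for(sp)
            harvestable = [r for r in stratum
                           if species_key(r.species) == key and r.dbh_cm >= mfd]
            share = len(harvestable) / all_stems if all_stems else 0.0
            profile = stem_form_profile(
                [r for r in stratum if species_key(r.species) == key],
                DEFAULT_DBH_CLASSES,
            )
            a = harvest_eligibility(
                sp, habitat, is_timber, form_by_species.get(sp, "Form 7"),
                density, policy, harvestable_share=share, profile=profile,
            )
            rows.append(
                {
                    "species": sp,
                    "habitat": habitat,
                    "is_timber": is_timber,
                    "form": form_by_species.get(sp, ""),
                    "mfd_cm": mfd,
                    "harvestable_density_per_ha": a.harvestable_density_per_ha,
                    "harvestable_share_of_stems": a.harvestable_share_of_stems,
                    "eligible": a.eligible,
                    "reasons": ";".join(a.reasons),
                }
            )
    return pd.DataFrame(rows)


def summarize_rarity(rarity: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per rarity form and per protection status."""
    n = len(rarity)
    rows = []
    for form, cnt in rarity["form"].value_counts().sort_index().items():
        rows.append({"dimension": "form", "level": form, "count": int(cnt),
                     "proportion": cnt / n,
                     "percent": int(round(100 * cnt / n))})
    for status, cnt in rarity["protection"].value_counts().sort_index().items():
        rows.append({"dimension": "protection", "level": status, "count": int(cnt),
                     "proportion": cnt / n,
                     "percent": int(round(100 * cnt / n))})
    rows.append({"dimension": "overall", "level": "rare", "count": int(rarity["is_rare"].sum()),
                 "proportion": rarity["is_rare"].mean(),
                 "percent": int(round(100 * rarity["is_rare"].mean()))})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle to ``config.outdir``.

    Returns the mapping of table name to written path.  Any stage error is
    re-raised as :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        result: InventoryReadResult = read_inventory(config.inventory, config.design)
    except Exception as exc:
        raise PipelineError(f"read_inventory: {exc}") from exc
    records = result.records
    if not records:
        raise PipelineError("read_inventory: no valid records in input")

    metadata = None
    if config.species_metadata:
        metadata = read_species_metadata(config.species_metadata)
        # statutory felling diameters override the policy default
        if "min_felling_dbh_cm" in metadata.columns:
            for key, row in metadata.iterrows():
                v = row["min_felling_dbh_cm"]
                if pd.notna(v):
                    config.policy.min_felling_dbh_cm[key] = float(v)

    paths: dict[str, Path] = {}

    def stage(name: str, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"{name}: {exc}") from exc

    rich = stage("richness", lambda: richness_table(records))
    _fmt(rich, outdir / "richness_by_habitat.csv")
    paths["richness"] = outdir / "richness_by_habitat.csv"

    pair, multi = stage("beta_diversity", lambda: beta_tables(records))
    _fmt(pair, outdir / "beta_pairwise.csv")
    _fmt(multi, outdir / "beta_multisite.csv")
    paths["beta_pairwise"] = outdir / "beta_pairwise.csv"
    paths["beta_multisite"] = outdir / "beta_multisite.csv"

    rarity = stage(
        "rarity_protection",
        lambda: rarity_table(records, config.thresholds, config.range_unit,
                             config.design, total_units=config.total_units),
    )
    _fmt(rarity, outdir / "species_rarity.csv")
    paths["rarity"] = outdir / "species_rarity.csv"

    summary = stage("summary", lambda: summarize_rarity(rarity))
    _fmt(summary, outdir / "rarity_summary.csv")
    paths["summary"] = outdir / "rarity_summary.csv"

    harvest = stage(
        "commercial",
        lambda: harvest_table(records, rarity, config.policy, config.design, metadata),
    )
    _fmt(harvest, outdir / "harvest_assessments.csv")
    paths["harvest"] = outdir / "harvest_assessments.csv"

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "inventory": str(config.inventory),
        "species_metadata": str(config.species_metadata) if config.species_metadata else None,
        "n_records": len(records),
        "n_rejected_rows": len(result.rejected),
        "warnings": result.warnings,
        "seed": config.seed,
        "unit": config.unit,
        "range_unit": config.range_unit,
        "design": {
            "plot_area_ha": config.design.plot_area_ha,
            "subplot_fraction": config.design.subplot_fraction,
            "small_tree_range_cm": list(config.design.small_tree_range_cm),
            "habitats": list(config.design.habitats),
        },
        "thresholds": {
            "wide_range_min_prop": config.thresholds.wide_range_min_prop,
            "habitat_various_min": config.thresholds.habitat_various_min,
            "abundance_large_min": config.thresholds.abundance_large_min,
            "abundance_scope": config.thresholds.abundance_scope,
        },
        "policy": {
            "default_mfd_cm": config.policy.default_mfd_cm,
            "min_harvest_density_per_ha": config.policy.min_harvest_density_per_ha,
            "allowed_habitats": sorted(config.policy.allowed_habitats),
            "require_common": config.policy.require_common,
        },
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
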