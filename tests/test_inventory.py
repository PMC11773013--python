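"""Inventory parsing, expansion factors, aggregation bookkeeping."""
import random

import pytest

from miombo.inventory import (
    SchemaError,
    SurveyDesign,
    TreeRecord,
    build_profiles,
    community_matrix,
    expansion_factor,
    read_inventory,
    stems_per_ha,
    write_inventory,
)

HEADER = "cluster,plot,habitat,protected_area,species,dbh_cm,stem_form\n"


def _write(tmp_path, body, header=HEADER):
    p = tmp_path / "inv.csv"
    p.write_text(header + body)
    return p


class TestReadInventory:
    def test_well_formed_file_parses_identically(self, tmp_path):
        p = _write(
            tmp_path,
            "C1,P1,humid,1,Brachystegia spiciformis,15.0,SF1\n"
            "C1,P2,semi-arid,no,Julbernardia globiflora,7.2,\n",
        )
        res = read_inventory(p)
        assert len(res.records) == 2
        assert not res.rejected and not res.warnings
        assert res.records[0].in_protected_area is True
        assert res.records[1].in_protected_area is False
        assert res.records[1].stem_form is None

    def test_small_dbh_row_rejected_with_row_and_field(self, tmp_path):
        p = _write(tmp_path, "C1,P1,humid,0,Acacia nigrescens,3.0,\n")
        res = read_inventory(p)
        assert not res.records
        (issue,) = res.rejected
        assert issue.row == 1 and issue.field == "dbh_cm"
        assert "3.0" in issue.message

    def test_unscored_large_stems_accepted_with_warning(self, tmp_path):
        p = _write(
            tmp_path,
            "C1,P1,humid,0,Afzelia quanzensis,12,\n"
            "C1,P1,humid,0,Afzelia quanzensis,14,\n"
            "C1,P2,humid,0,Afzelia quanzensis,25,SF2\n",
        )
        res = read_inventory(p)
        assert len(res.records) == 3
        assert len(res.warnings) == 1
        assert "2 stem(s)" in res.warnings[0]

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("cluster,plot,species,dbh_cm\nC1,P1,x,12\n")
        with pytest.raises(SchemaError, match="habitat"):
            read_inventory(p)

    def test_unknown_habitat_rejected_unless_registered(self, tmp_path):
        p = _write(tmp_path, "C1,P1,montane,0,Uapaca kirkiana,12,SF1\n")
        assert read_inventory(p).rejected[0].field == "habitat"
        wide = SurveyDesign(habitats=("humid", "semi-arid", "rainy", "montane"))
        assert len(read_inventory(p, wide).records) == 1

    def test_tab_delimiter_autodetected(self, tmp_path):
        p = tmp_path / "inv.tsv"
        p.write_text(HEADER.replace(",", "\t") + "C1\tP1\thumid\t1\tPterocarpus angolensis\t41\tSF3\n")
        assert len(read_inventory(p).records) == 1

    def test_roundtrip_through_write_inventory(self, tmp_path, make_record):
        records = [make_record(), make_record(plot_id="P2", dbh_cm=7.0, stem_form=None)]
        p = tmp_path / "out.csv"
        write_inventory(records, p)
        assert read_inventory(p).records == records


class TestRecordValidation:
    def test_stem_form_requires_large_dbh(self):
        with pytest.raises(ValueError, match="stem_form"):
            TreeRecord("C1", "P1", "humid", False, "X y", 7.0, stem_form="SF1")

    def test_empty_species_rejected(self, make_record):
        with pytest.raises(ValueError, match="species"):
            make_record(species="  ")


class TestExpansionFactor:
    @pytest.mark.parametrize(
        "dbh, expected",
        [(7.0, 4.0), (5.0, 4.0), (9.9, 4.0), (10.0, 1.0), (55.0, 1.0)],
    )
    def test_subplot_weight_on_halfopen_range(self, make_record, design, dbh, expected):
        r = make_record(dbh_cm=dbh, stem_form="SF1" if dbh >= 10 else None)
        assert expansion_factor(r, design) == expected

    def test_below_census_threshold_errors(self, design):
        r = TreeRecord("C1", "P1", "humid", False, "X y", 6.0)
        tight = SurveyDesign(small_tree_range_cm=(8.0, 10.0))
        with pytest.raises(ValueError, match="census threshold"):
            expansion_factor(r, tight)


class TestStemsPerHa:
    def test_large_stems_density(self, make_record, design):
        recs = [make_record(dbh_cm=20 + i) for i in range(12)]
        assert stems_per_ha(recs, n_plots=30, design=design) == pytest.approx(4.0)

    def test_small_stem_expanded(self, make_record, design):
        recs = [make_record(dbh_cm=7.0, stem_form=None)]
        assert stems_per_ha(recs, n_plots=1, design=design) == pytest.approx(40.0)

    def test_empty_is_zero_and_zero_plots_errors(self, design):
        assert stems_per_ha([], 5, design) == 0.0
        with pytest.raises(ValueError):
            stems_per_ha([], 0, design)

    def test_linearity_in_record_multiplicity(self, make_record, design):
        recs = [make_record(dbh_cm=d, stem_form=None if d < 10 else "SF1")
                for d in (6.0, 12.0, 44.0)]
        d1 = stems_per_ha(recs, 10, design)
        d2 = stems_per_ha(recs + recs, 10, design)
        assert d2 == pytest.approx(2 * d1)


class TestBuildProfiles:
    def test_occurrences_are_plot_level_presences(self, make_record):
        recs = [
            make_record(plot_id="P1", in_protected_area=True),
            make_record(plot_id="P1", in_protected_area=True),
            make_record(plot_id="P2", in_protected_area=False),
        ]
        prof = build_profiles(recs, unit="cluster")["Brachystegia spiciformis"]
        assert prof.occurrences_total == 2
        assert prof.occurrences_in_pa == 1
        assert prof.occupied_units == 1
        assert prof.total_abundance == 3

    def test_empty_input_gives_empty_map(self):
        assert build_profiles([]) == {}

    def test_conservation_of_records_and_occurrences(self, make_record):
        rng = random.Random(42)
        recs = [
            make_record(
                cluster_id=f"C{rng.randrange(4)}",
                plot_id=f"P{rng.randrange(3)}",
                species=f"Species {rng.randrange(6)}",
                habitat=rng.choice(["humid", "rainy"]),
                in_protected_area=rng.random() < 0.3,
            )
            for _ in range(200)
        ]
        profiles = build_profiles(recs, unit="plot")
        assert sum(p.total_abundance for p in profiles.values()) == len(recs)
        pairs = {(r.plot_key, r.species) for r in recs}
        assert sum(p.occurrences_total for p in profiles.values()) == len(pairs)


class TestCommunityMatrix:
    def test_counts_and_row_sums(self, make_record):
        recs = (
            [make_record(habitat="humid", species="s1")] * 2
            + [make_record(habitat="humid", species="s2")]
            + [make_record(habitat="rainy", species="s3")] * 5
        )
        cm = community_matrix(recs, "habitat")
        df = cm.to_frame()
        assert df.loc["humid", "s1"] == 2
        assert df.loc["rainy", "s3"] == 5
        assert list(df.sum(axis=1)) == [3, 5]

    def test_presence_mode_is_indicator(self, make_record):
        recs = [make_record(species="s1")] * 3 + [make_record(species="s2")]
        pres = community_matrix(recs, "habitat").presence()
        assert set(pres.values.ravel()) <= {0, 1}
        assert pres.site_set("humid") == {"s1", "s2"}

    def test_input_order_invariance(self, make_record):
        rng = random.Random(7)
        recs = [
            make_record(habitat=rng.choice(["humid", "rainy", "semi-arid"]),
                        species=f"s{rng.randrange(5)}")
            for _ in range(60)
        ]
        cm1 = community_matrix(recs, "habitat")
        shuffled = recs[:]
        rng.shuffle(shuffled)
        cm2 = community_matrix(shuffled, "habitat")
        assert cm1.sites == cm2.sites and cm1.species == cm2.species
        assert (cm1.values == cm2.values).all()
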