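"""Harvestable densities, stem-form profiles, eligibility rule."""
import math

import numpy as np
import pytest

from miombo.commercial import (
    DEFAULT_DBH_CLASSES,
    TimberPolicy,
    harvest_eligibility,
    harvestable_density,
    stem_form_profile,
)
from miombo.inventory import SurveyDesign, TreeRecord


def rec(species="Afzelia quanzensis", dbh=45.0, form="SF1", habitat="humid"):
    return TreeRecord("C1", "P1", habitat, False, species, dbh,
                      stem_form=form if dbh >= 10 else None)


class TestHarvestableDensity:
    def test_density_over_stratum_area(self, design):
        records = [rec(dbh=40 + i) for i in range(8)] + [rec(dbh=25)] * 5
        d = harvestable_density("Afzelia quanzensis", records, 20, TimberPolicy(), design)
        assert d == pytest.approx(8 / 2.0)

    def test_no_harvestable_trees_gives_zero(self, design):
        records = [rec(dbh=25), rec(dbh=39.9)]
        assert harvestable_density("Afzelia quanzensis", records, 20, TimberPolicy(), design) == 0.0

    def test_mfd_override_admits_smaller_trees(self, design):
        records = [rec(dbh=35)]
        default = TimberPolicy()
        lowered = TimberPolicy(min_felling_dbh_cm={"Afzelia quanzensis": 30.0})
        assert harvestable_density("Afzelia quanzensis", records, 10, default, design) == 0.0
        assert harvestable_density("afzelia  quanzensis", records, 10, lowered, design) > 0.0

    def test_raising_mfd_never_increases_density(self, design):
        rng = np.random.default_rng(3)
        records = [rec(dbh=float(d)) for d in rng.uniform(10, 80, size=100)]
        dens = [
            harvestable_density("Afzelia quanzensis", records, 50,
                                TimberPolicy(default_mfd_cm=m), design)
            for m in (20, 30, 40, 50, 60)
        ]
        assert all(a >= b for a, b in zip(dens, dens[1:]))


class TestStemFormProfile:
    def test_relative_frequencies(self):
        records = [rec(dbh=15, form=f) for f in ("SF1", "SF1", "SF1", "SF2")]
        prof = stem_form_profile(records)
        assert prof[(10.0, 20.0)] == pytest.approx((0.75, 0.25, 0.0))

    def test_empty_class_absent_not_zero_filled(self):
        records = [rec(dbh=15), rec(dbh=45)]
        prof = stem_form_profile(records)
        assert (30.0, 40.0) not in prof
        assert (10.0, 20.0) in prof and (40.0, math.inf) in prof

    def test_unscored_stems_excluded(self):
        records = [rec(dbh=15), TreeRecord("C1", "P1", "humid", False, "X y", 15.0)]
        prof = stem_form_profile(records)
        assert prof[(10.0, 20.0)] == (1.0, 0.0, 0.0)

    def test_bad_class_edges_error(self):
        with pytest.raises(ValueError):
            stem_form_profile([], classes=(10, 30, 20))

    def test_profile_recovers_sampling_probabilities(self):
        # multinomial(n=5000, p=(0.74, 0.17, 0.09)); each share within its
        # 99.9 % normal band (half-width 3.29 * sqrt(p(1-p)/n))
        rng = np.random.default_rng(12)
        p = (0.74, 0.17, 0.09)
        forms = rng.choice(["SF1", "SF2", "SF3"], size=5000, p=p)
        records = [rec(dbh=15, form=f) for f in forms]
        prof = stem_form_profile(records)[(10.0, 20.0)]
        for share, pi in zip(prof, p):
            half = 3.29 * math.sqrt(pi * (1 - pi) / 5000)
            assert abs(share - pi) < half


class TestEligibility:
    def test_common_timber_in_humid_at_density_is_eligible(self):
        a = harvest_eligibility("Brachystegia spiciformis", "humid", True,
                                "Common", 4.0, TimberPolicy())
        assert a.eligible and a.reasons == []

    def test_rare_form_blocks_harvest(self):
        a = harvest_eligibility("X y", "humid", True, "Form 4", 2.0, TimberPolicy())
        assert not a.eligible and a.reasons == ["RARE_FORM"]

    def test_single_habitat_form_also_fails_generalist_rule(self):
        a = harvest_eligibility("X y", "humid", True, "Form 2", 2.0, TimberPolicy())
        assert set(a.reasons) == {"RARE_FORM", "NOT_GENERALIST"}

    def test_habitat_restriction(self):
        a = harvest_eligibility("X y", "semi-arid", True, "Common", 3.0, TimberPolicy())
        assert a.reasons == ["HABITAT_RESTRICTED"]

    def test_low_density(self):
        a = harvest_eligibility("X y", "humid", True, "Common", 0.2, TimberPolicy())
        assert a.reasons == ["LOW_DENSITY"]

    def test_zero_density_reported_as_no_harvestable_trees(self):
        a = harvest_eligibility("X y", "humid", True, "Common", 0.0, TimberPolicy())
        assert a.reasons == ["NO_HARVESTABLE_TREES"]

    def test_all_failed_conditions_reported(self):
        a = harvest_eligibility("X y", "rainy", False, "Form 7", 0.1, TimberPolicy())
        assert set(a.reasons) == {
            "NOT_TIMBER", "RARE_FORM", "NOT_GENERALIST",
            "HABITAT_RESTRICTED", "LOW_DENSITY",
        }

    def test_removing_sole_failed_condition_flips_eligibility(self):
        # LOW_DENSITY is the only failure; lowering the floor flips it
        strict = TimberPolicy(min_harvest_density_per_ha=1.0)
        lax = TimberPolicy(min_harvest_density_per_ha=0.1)
        args = ("X y", "humid", True, "Common", 0.5)
        assert not harvest_eligibility(*args, strict).eligible
        assert harvest_eligibility(*args, lax).eligible

    def test_raising_density_floor_never_enables(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            density = float(rng.uniform(0, 5))
            form = rng.choice(["Common", "Form 1", "Form 6"])
            timber = bool(rng.random() < 0.8)
            habitat = rng.choice(["humid", "semi-arid"])
            lo = harvest_eligibility("X y", habitat, timber, form, density,
                                     TimberPolicy(min_harvest_density_per_ha=0.5))
            hi = harvest_eligibility("X y", habitat, timber, form, density,
                                     TimberPolicy(min_harvest_density_per_ha=2.0))
            assert not (hi.eligible and not lo.eligible)
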