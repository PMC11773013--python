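import pytest

from miombo.inventory import SurveyDesign, TreeRecord


@pytest.fixture
def design():
    return SurveyDesign()


@pytest.fixture
def make_record():
    """Factory for valid records with overridable fields."""

    def _make(**kw):
        base = dict(
            cluster_id="C1",
            plot_id="P1",
            habitat="humid",
            in_protected_area=False,
            species="Brachystegia spiciformis",
            dbh_cm=15.0,
            stem_form="SF1",
        )
        base.update(kw)
        if base["dbh_cm"] < 10:
            base.setdefault("stem_form", None)
            if base["stem_form"] is not None and "stem_form" not in kw:
                base["stem_form"] = None
        return TreeRecord(**base)

    return _make
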