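"""Reaction operators and the packaged enzyme-activity panels."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pufapath.enzymes import (
    ActivityError,
    ActivityRecord,
    Conversion,
    ConversionStatus,
    EnzymeKind,
    apply_desaturation,
    apply_elongation,
    export_activity_csv,
    load_activity_panels,
)
from pufapath.nomenclature import (
    FattyAcid,
    classify_unsaturation,
    parse_shorthand,
    to_delta_string,
    to_omega,
)

from test_nomenclature import fatty_acids


@pytest.mark.parametrize(
    "substrate, product",
    [
        ("18:3n-3", "20:3n-3"),  # Δ{9,12,15} -> Δ{11,14,17}
        ("16:1n-7", "18:1n-7"),
        ("18:0", "20:0"),
        ("22:5n-3", "24:5n-3"),
    ],
)
def test_elongation_adds_two_carbons_at_carboxyl_end(substrate, product):
    fa = apply_elongation(parse_shorthand(substrate))
    assert fa == parse_shorthand(product)


def test_elongation_preserves_omega_class():
    assert to_omega(apply_elongation(parse_shorthand("18:3n-3"))) == "20:3n-3"
    assert apply_elongation(parse_shorthand("18:3n-3")).double_bonds == (11, 14, 17)


def test_elongation_respects_chain_cap():
    with pytest.raises(ActivityError):
        apply_elongation(parse_shorthand("24:0"))
    assert apply_elongation(parse_shorthand("24:0"), cap=26).chain_length == 26


@pytest.mark.parametrize(
    "substrate, d, product",
    [
        ("20:1n-9", 5, "20:2^Δ5,11^"),
        ("20:2n-6", 8, "20:3n-6"),
        ("18:0", 5, "18:1n-13"),
    ],
)
def test_desaturation_inserts_position(substrate, d, product):
    assert apply_desaturation(parse_shorthand(substrate), d) == parse_shorthand(product)


@pytest.mark.parametrize(
    "substrate, d",
    [
        ("20:2^Δ5,11^", 5),  # duplicate
        ("20:1n-9", 10),  # adjacent to Δ11
        ("20:1n-9", 25),  # outside the chain
        ("20:1n-9", 1),
    ],
)
def test_desaturation_rejects_impossible_positions(substrate, d):
    with pytest.raises(ActivityError):
        apply_desaturation(parse_shorthand(substrate), d)


@settings(deadline=None, max_examples=200)
@given(fatty_acids(max_chain=22))
def test_elongation_never_changes_unsaturation_class(fa):
    assert classify_unsaturation(apply_elongation(fa)) is classify_unsaturation(fa)


@settings(deadline=None, max_examples=200)
@given(fatty_acids(max_chain=22), st.integers(2, 23))
def test_elongation_commutes_with_desaturation(fa, d):
    """elongate(desaturate(fa, d)) == desaturate(elongate(fa), d + 2)."""
    try:
        left = apply_elongation(apply_desaturation(fa, d))
    except ActivityError:
        return
    assert left == apply_desaturation(apply_elongation(fa), d + 2)
    assert left.n_double_bonds == fa.n_double_bonds + 1


class TestActivityFixture:
    def test_panel_census(self, panels):
        by_kind = {}
        for p in panels:
            by_kind.setdefault(p.kind, []).append(p.name)
        assert len(by_kind[EnzymeKind.ELONGASE]) == 13
        assert len(by_kind[EnzymeKind.DESATURASE]) == 3
        smufa = [n for n in by_kind[EnzymeKind.ELONGASE] if n.startswith("Elovl6-like")]
        assert len(smufa) == 8
        assert set(by_kind[EnzymeKind.DESATURASE]) == {"FadsA", "FadsC1", "FadsC2"}

    def test_every_row_satisfies_its_operator(self, panels):
        for panel in panels:
            for rec in panel.records:
                assert rec.product == rec.expected_product()

    @pytest.mark.parametrize(
        "enzyme, substrate, product, percent, label",
        [
            ("FadsC2", "20:2n-6", "20:3n-6", 40.5, "Δ8"),
            ("Elovl1/7-like", "22:5n-3", "24:5n-3", 14.7, "C22→C24"),
            ("FadsA", "20:1n-9", "20:2^Δ5,11^", 35.1, "Δ5"),
            ("FadsA", "20:3n-6", "20:4n-6", 50.2, "Δ5"),
            ("Elovl6-like C", "18:3n-3", "20:3n-3", 58.5, "C18→C20"),
        ],
    )
    def test_measured_rows(self, panels, enzyme, substrate, product, percent, label):
        panel = next(p for p in panels if p.name == enzyme)
        rec = next(
            r for r in panel.records if r.substrate == parse_shorthand(substrate)
            and r.activity_label == label
        )
        assert rec.product == parse_shorthand(product)
        assert rec.conversion == Conversion(ConversionStatus.MEASURED, percent)

    def test_not_detected_is_a_distinct_flag(self, panels):
        panel = next(p for p in panels if p.name == "Elovl6-like A")
        rec = next(r for r in panel.records if r.substrate == parse_shorthand("22:4n-6"))
        assert rec.conversion.status is ConversionStatus.NOT_DETECTED
        assert rec.conversion.percent is None

    def test_qualitative_rows_present(self, panels):
        elovl6c = next(p for p in panels if p.name == "Elovl6-like C")
        quals = [r for r in elovl6c.records if r.conversion.status is ConversionStatus.QUALITATIVE]
        assert {str(r.substrate) for r in quals} == {
            to_delta_string(parse_shorthand(s)) for s in ("16:1n-7", "18:1n-7", "18:1n-9")
        }
        fadsa = next(p for p in panels if p.name == "FadsA")
        stearate = next(r for r in fadsa.records if r.substrate == parse_shorthand("18:0"))
        assert stearate.conversion.status is ConversionStatus.QUALITATIVE
        assert to_omega(stearate.product) == "18:1n-13"

    def test_fads_regioselectivity_annotation(self, panels):
        assert {p.name: p.regioselectivity for p in panels if p.kind is EnzymeKind.DESATURASE} == {
            "FadsA": 5,
            "FadsC1": 8,
            "FadsC2": 8,
        }

    def test_corrupt_fixture_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text(
            "enzyme,kind,substrate,product,conversion,activity_label\n"
            "FadsX,desaturase,20:3n-6,20:4n-3,12.0,Δ5\n",
            encoding="utf-8",
        )
        with pytest.raises(ActivityError):
            load_activity_panels(bad)

    def test_export_round_trips(self, panels, tmp_path):
        out = tmp_path / "panels.csv"
        export_activity_csv(panels, out)
        reloaded = load_activity_panels(out)
        assert {p.name for p in reloaded} == {p.name for p in panels}
        assert sum(len(p.records) for p in reloaded) == sum(len(p.records) for p in panels)
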