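"""Design bundles: recipe fidelity, validation rules, economy, oligo output."""

import dataclasses

import pytest

from origamod.builder import (
    build_design,
    economy_metrics,
    emit_oligos,
    interaction_matrix_signature,
    oligos_to_dataframe,
    placeholder_anchor_map,
    validate_design,
)
from origamod.geometry import StructureKind, TargetStructure
from origamod.sequences import StickyEnd
from tests.conftest import BUILD_SEED


def species_by_id(bundle):
    return {sp.species_id: sp for sp in bundle.species}


def face(bundle, species, face_id):
    return next(f for f in species_by_id(bundle)[species].faces if f.face_id == face_id)


class TestRecipeFidelity:
    def test_all_demonstrated_recipes_validate_clean(self, all_recipe_bundles):
        for name, bundle in all_recipe_bundles.items():
            report = validate_design(bundle)
            assert report.ok, (name, report.violations)

    def test_continuous_tiling_recipe(self, all_recipe_bundles):
        b = all_recipe_bundles["continuous_tiling"]
        assert len(b.species) == 1
        for f in b.species[0].faces:
            assert f.bond_label == "sA"
            assert (f.angle_module.l_top, f.angle_module.l_bottom) == (3, 3)
        bc = b.bond_classes["sA"]
        assert (bc.top_bp, bc.bottom_bp) == (5, 5)
        assert b.assembly_conditions.temperature_C == 28.0
        assert b.assembly_conditions.time_h == 36.0

    def test_tetramer_tiling_recipe(self, all_recipe_bundles):
        b = all_recipe_bundles["tetramer_tiling"]
        ratios = {sp.species_id: sp.stoichiometry for sp in b.species}
        assert ratios == {"yellow": 3.0, "green": 1.0}
        assert [f.bond_label for f in species_by_id(b)["yellow"].faces] == ["A", "A*", "B"]
        assert [f.bond_label for f in species_by_id(b)["green"].faces] == ["B*"] * 3

    def test_t1_recipe(self, all_recipe_bundles):
        b = all_recipe_bundles["shell_T1"]
        assert len(b.species) == 1
        assert b.subunits_per_structure() == 20
        for f in b.species[0].faces:
            assert (f.angle_module.l_top, f.angle_module.l_bottom) == (14, 3)
        bc = b.bond_classes["sA"]
        assert bc.self_complementary
        assert (bc.top_bp, bc.bottom_bp) == (6, 5)
        assert (b.assembly_conditions.temperature_C, b.assembly_conditions.time_h) == (25.0, 24.0)

    def test_t4_recipe(self, all_recipe_bundles):
        b = all_recipe_bundles["shell_T4"]
        assert b.subunits_per_structure() == 80
        ratios = {sp.species_id: sp.stoichiometry for sp in b.species}
        assert ratios == {"yellow": 3.0, "green": 1.0}
        y = species_by_id(b)["yellow"]
        mods = {f.face_id: (f.angle_module.l_top, f.angle_module.l_bottom) for f in y.faces}
        assert mods == {"S1": (14, 3), "S2": (14, 3), "S3": (3, 3)}
        # the intra-tetramer bond is hierarchical (stronger, 7 bp) than A-A*
        assert b.bond_classes["B"].hierarchical
        assert b.bond_classes["B"].top_bp == 7 > b.bond_classes["A"].top_bp == 6
        assert b.bond_classes["A"].bottom_bp == 5
        assert (b.assembly_conditions.temperature_C, b.assembly_conditions.time_h) == (30.0, 96.0)

    def test_tube_recipe(self, all_recipe_bundles):
        b = all_recipe_bundles["tube_m6"]
        assert [sp.stoichiometry for sp in b.species] == [1.0, 1.0, 1.0]
        assert b.subunits_per_structure() == 18
        purple_s3 = face(b, "purple", "S3")
        assert not purple_s3.active
        for sp in ("yellow", "green"):
            s3 = face(b, sp, "S3")
            assert (s3.angle_module.l_top, s3.angle_module.l_bottom) == (3, 8)
            for fid in ("S1", "S2"):
                f = face(b, sp, fid)
                assert (f.angle_module.l_top, f.angle_module.l_bottom) == (14, 3)

    def test_vertex_recipes(self):
        b5 = build_design(TargetStructure(StructureKind.VERTEX, n_fold=5), seed=BUILD_SEED)
        assert len(b5.species) == 1
        assert not face(b5, "yellow", "S3").active
        assert validate_design(b5).ok
        b6 = build_design(TargetStructure(StructureKind.VERTEX, n_fold=6), seed=BUILD_SEED)
        assert len(b6.species) == 2  # forced alternation: only even rings close
        assert validate_design(b6).ok

    def test_single_flexible_module_t4(self):
        b = build_design(
            TargetStructure(StructureKind.SHELL, T=4),
            seed=BUILD_SEED,
            single_angle_module=True,
        )
        for sp in b.species:
            for f in sp.faces:
                assert (f.angle_module.l_top, f.angle_module.l_bottom) == (14, 3)
        assert validate_design(b).ok

    def test_unsupported_target_lists_supported_kinds(self):
        with pytest.raises(ValueError, match="supported"):
            build_design(TargetStructure(StructureKind.SHELL, T=9), seed=0)


class TestInteractionMatrixReuse:
    def test_tetramer_matrix_equals_t4(self, all_recipe_bundles):
        sig_2d = interaction_matrix_signature(all_recipe_bundles["tetramer_tiling"])
        sig_3d = interaction_matrix_signature(all_recipe_bundles["shell_T4"])
        assert sig_2d == sig_3d

    def test_continuous_matrix_equals_t1(self, all_recipe_bundles):
        sig_2d = interaction_matrix_signature(all_recipe_bundles["continuous_tiling"])
        sig_3d = interaction_matrix_signature(all_recipe_bundles["shell_T1"])
        assert sig_2d == sig_3d


class TestValidation:
    def test_duplicate_row_label_is_anti_offset_violation(self, t4_bundle):
        b = dataclasses.replace(t4_bundle)
        b.species = [dataclasses.replace(sp) for sp in t4_bundle.species]
        sp = b.species[0]
        sp.faces = [dataclasses.replace(f) for f in sp.faces]
        f = sp.faces[0]
        f.top_sticky = [f.top_sticky[0]] * 2 + f.top_sticky[2:]
        report = validate_design(b)
        assert any("anti-offset" in v for v in report.violations)

    def test_missing_partner_is_closure_violation(self, t4_bundle):
        b = dataclasses.replace(t4_bundle)
        b.species = [dataclasses.replace(sp) for sp in t4_bundle.species]
        # drop the green species: B loses its B* partner faces
        b.species = [sp for sp in b.species if sp.species_id == "yellow"]
        report = validate_design(b)
        assert any("closure" in v and "B" in v for v in report.violations)

    def test_corrupted_sticky_set_flagged(self, t4_bundle):
        b = dataclasses.replace(t4_bundle)
        ends = list(t4_bundle.sticky_set.ends)
        bad = StickyEnd(ends[0].label, ends[2].sequence, ends[0].partner_label)
        b.sticky_set = dataclasses.replace(t4_bundle.sticky_set, ends=[bad] + ends[1:])
        report = validate_design(b)
        assert any("sequence set" in v for v in report.violations)


class TestEconomyMetrics:
    def test_fully_active_subunit(self, t4_bundle):
        m = economy_metrics(t4_bundle)
        assert m.max_variable_strands == 24
        assert m.total_staples == 204
        assert m.max_modified_fraction_pct == pytest.approx(100 * 24 / 204)
        assert m.max_modified_fraction_pct <= 12.0

    def test_passivated_face_reduces_count(self, all_recipe_bundles):
        m = economy_metrics(all_recipe_bundles["tube_m6"])
        assert m.per_species["purple"]["variable_strands"] == 16
        assert m.per_species["yellow"]["variable_strands"] == 24


class TestEmitOligos:
    def test_strand_counts_match_economy(self, all_recipe_bundles):
        for name, bundle in all_recipe_bundles.items():
            m = economy_metrics(bundle)
            expected = sum(
                int(v["variable_strands"]) for v in m.per_species.values()
            )
            assert len(emit_oligos(bundle)) == expected, name

    def test_sequence_composition(self, all_recipe_bundles):
        b = all_recipe_bundles["shell_T1"]
        records = emit_oligos(b)
        sticky = b.sticky_by_label()
        anchors = placeholder_anchor_map()
        rec = next(r for r in records if r.face == "S1" and r.row == "top" and r.position == 1)
        lab = face(b, "yellow", "S1").top_sticky[0]
        assert rec.sequence == anchors["S1.top.1"] + "T" * 14 + sticky[lab].sequence
        assert len(sticky[lab].sequence) == 6
        bot = next(r for r in records if r.row == "bottom" and r.position == 1 and r.face == "S1")
        assert "T" * 3 in bot.sequence
        assert len(sticky[face(b, "yellow", "S1").bottom_sticky[0]].sequence) == 5

    def test_passivated_face_emits_nothing(self, all_recipe_bundles):
        records = emit_oligos(all_recipe_bundles["tube_m6"])
        assert not [r for r in records if r.species == "purple" and r.face == "S3"]

    def test_deterministic_and_rebuildable(self, all_recipe_bundles):
        b1 = all_recipe_bundles["shell_T4"]
        b2 = build_design(TargetStructure(StructureKind.SHELL, T=4), seed=BUILD_SEED)
        assert oligos_to_dataframe(emit_oligos(b1)).equals(
            oligos_to_dataframe(emit_oligos(b2))
        )

    def test_missing_anchor_raises(self, t4_bundle):
        partial = placeholder_anchor_map()
        del partial["S1.top.1"]
        with pytest.raises(ValueError, match="missing anchor"):
            emit_oligos(t4_bundle, partial)


class TestSerialization:
    def test_bundle_json_round_trip_fields(self, t4_bundle, tmp_path):
        import json

        path = tmp_path / "bundle.json"
        t4_bundle.to_json(path)
        doc = json.loads(path.read_text())
        assert doc["schema_version"] == 1
        assert doc["target"] == {"kind": "shell", "T": 4}
        assert {s["species_id"] for s in doc["species"]} == {"yellow", "green"}
        assert len(doc["sticky_ends"]) == len(t4_bundle.sticky_set.ends)
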