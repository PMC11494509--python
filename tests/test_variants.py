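"""Charge-variant algebra: atrophy, restoration, mutation, λ-scaling."""

import numpy as np
import pytest

from preorg import (
    ChargeVariantSpec,
    apply_atrophy,
    build_variant,
    decompose_by_residue,
    load_default_library,
    mutate_charges,
    potential_at_point,
    restore_residues,
    scale_residue,
)
from preorg.structures import ResidueKey
from preorg.variants import DEFAULT_LAMBDA_GRID
from .conftest import brute_force_decomposition

ORIGIN = np.zeros(3)


@pytest.fixture
def keys(toy_structure):
    return {k.residue_name: k for k in toy_structure.residues()}


class TestAtrophy:
    def test_environment_potential_is_zero(self, toy_structure, keys):
        keep = [keys["LYS"]]
        v = apply_atrophy(toy_structure, keep)
        env = potential_at_point(
            v, ORIGIN, include={"protein", "water", "ion"}, exclude_residues=set(keep)
        )
        assert env == 0.0

    def test_keep_list_charges_bit_identical(self, toy_structure, keys):
        keep = [keys["LYS"], keys["ASP"]]
        v = apply_atrophy(toy_structure, keep)
        for a, b in zip(toy_structure.atoms, v.atoms):
            if a.residue_key in keep or a.group_kind == "substrate":
                assert b.charge == a.charge  # bit-exact, no arithmetic applied
            else:
                assert b.charge == 0.0

    def test_decomposition_nonzero_only_for_keep_and_substrate(self, toy_structure, keys):
        keep = {keys["LYS"]}
        v = apply_atrophy(toy_structure, keep)
        d = decompose_by_residue(v, ORIGIN)
        nonzero = {k for k, c in d.per_group.items() if c != 0.0}
        allowed = keep | {k for k in v.residues() if k.residue_name == "SAL"}
        assert nonzero <= allowed

    def test_idempotent(self, toy_structure, keys):
        keep = [keys["LYS"]]
        once = apply_atrophy(toy_structure, keep)
        twice = apply_atrophy(once, keep)
        assert [a.charge for a in twice.atoms] == [a.charge for a in once.atoms]

    def test_coordinates_and_identity_untouched(self, toy_structure, keys):
        v = apply_atrophy(toy_structure, [keys["LYS"]])
        np.testing.assert_array_equal(v.positions(), toy_structure.positions())
        assert [a.key for a in v.atoms] == [a.key for a in toy_structure.atoms]

    def test_unknown_keep_residue_is_error(self, toy_structure):
        with pytest.raises(KeyError):
            apply_atrophy(toy_structure, [ResidueKey("Z", 999, "ASP")])


class TestRestore:
    def test_restore_all_reproduces_original(self, toy_structure, keys):
        atro = apply_atrophy(toy_structure, [])
        back = restore_residues(atro, toy_structure, list(toy_structure.residues()))
        assert [a.charge for a in back.atoms] == [a.charge for a in toy_structure.atoms]

    def test_restore_one_changes_only_that_residue(self, toy_structure, keys):
        atro = apply_atrophy(toy_structure, [])
        v = restore_residues(atro, toy_structure, [keys["ASP"]])
        for a, o, z in zip(v.atoms, toy_structure.atoms, atro.atoms):
            expected = o.charge if a.residue_key == keys["ASP"] else z.charge
            assert a.charge == expected

    def test_sequential_equals_single_call(self, toy_structure, keys):
        atro = apply_atrophy(toy_structure, [])
        seq = restore_residues(
            restore_residues(atro, toy_structure, [keys["ASP"]]),
            toy_structure,
            ["waters"],
        )
        joint = restore_residues(atro, toy_structure, [keys["ASP"], "waters"])
        assert [a.charge for a in seq.atoms] == [a.charge for a in joint.atoms]

    def test_atom_mismatch_is_error(self, toy_structure, keys):
        atro = apply_atrophy(toy_structure, [])
        truncated = type(toy_structure)(
            [a for a in toy_structure.atoms][:-1], toy_structure.title
        )
        with pytest.raises(ValueError, match="atom-aligned"):
            restore_residues(atro, truncated, [keys["ASP"]])


class TestMutation:
    def test_self_mutation_is_identity(self):
        from .conftest import library_asp_structure

        s = library_asp_structure()
        key = next(iter(s.residues()))
        v = mutate_charges(s, key, "ASP", load_default_library())
        assert [a.charge for a in v.atoms] == [a.charge for a in s.atoms]
        assert v.residue_net_charge(key) == pytest.approx(-1.0, abs=1e-6)

    def test_asp_to_ala_neutralizes(self):
        from .conftest import library_asp_structure

        s = library_asp_structure()
        key = next(iter(s.residues()))
        lib = load_default_library()
        v = mutate_charges(s, key, "ALA", lib)
        # backbone + CB take Ala charges; OD1/OD2/CG absent from the
        # Ala template are zeroed -> net formal charge 0
        assert v.residue_net_charge(key) == pytest.approx(0.0, abs=1e-6)
        by_name = {a.atom_name: a.charge for a in v.atoms}
        assert by_name["OD1"] == 0.0 and by_name["OD2"] == 0.0

    def test_asp_to_glu_keeps_negative_charge(self):
        from .conftest import library_asp_structure

        s = library_asp_structure()
        key = next(iter(s.residues()))
        v = mutate_charges(s, key, "GLU", load_default_library())
        # shared atoms take Glu charges, OD1/OD2 are zeroed, and the
        # charge of coordinate-less Glu atoms (CD/OE1/OE2) folds onto
        # the last matched atom, landing on Glu's formal net of -1
        assert v.residue_net_charge(key) == pytest.approx(-1.0, abs=1e-6)

    def test_geometry_untouched(self, toy_structure, keys):
        lib = load_default_library()
        v = mutate_charges(toy_structure, keys["ASP"], "GLU", lib)
        np.testing.assert_array_equal(v.positions(), toy_structure.positions())

    def test_unknown_target_is_error(self, toy_structure, keys):
        with pytest.raises(KeyError, match="XYZ"):
            mutate_charges(toy_structure, keys["ASP"], "XYZ", load_default_library())

    def test_potential_change_matches_brute_force_resum(self, toy_structure, keys):
        lib = load_default_library()
        v = mutate_charges(toy_structure, keys["ASP"], "GLU", lib)
        d = decompose_by_residue(v, ORIGIN)
        oracle = brute_force_decomposition(v, ORIGIN)
        for key, val in d.per_group.items():
            assert val == pytest.approx(oracle[key], rel=1e-8)


class TestLambdaScaling:
    def test_lambda_one_is_identity(self, toy_structure, keys):
        v = scale_residue(toy_structure, keys["ASP"], 1.0)
        assert [a.charge for a in v.atoms] == [a.charge for a in toy_structure.atoms]

    def test_lambda_zero_zeroes_residue(self, toy_structure, keys):
        v = scale_residue(toy_structure, keys["ASP"], 0.0)
        assert v.residue_net_charge(keys["ASP"]) == 0.0

    @pytest.mark.parametrize("lam", DEFAULT_LAMBDA_GRID)
    def test_contribution_linear_in_lambda(self, toy_structure, keys, lam):
        base = decompose_by_residue(toy_structure, ORIGIN).per_group[keys["ASP"]]
        v = scale_residue(toy_structure, keys["ASP"], lam)
        scaled = decompose_by_residue(v, ORIGIN).per_group[keys["ASP"]]
        assert scaled == pytest.approx(lam * base, rel=1e-12, abs=1e-12)

    def test_composition_multiplies(self, toy_structure, keys):
        v1 = scale_residue(scale_residue(toy_structure, keys["ASP"], 0.5), keys["ASP"], 0.6)
        v2 = scale_residue(toy_structure, keys["ASP"], 0.3)
        for a, b in zip(v1.atoms, v2.atoms):
            assert a.charge == pytest.approx(b.charge, rel=1e-12)

    def test_negative_lambda_rejected(self, toy_structure, keys):
        with pytest.raises(ValueError):
            scale_residue(toy_structure, keys["ASP"], -0.1)


class TestBuildVariant:
    def test_empty_spec_is_identity_with_on_label(self, toy_structure):
        v, label = build_variant(toy_structure, ChargeVariantSpec())
        assert label == "Velec(ON)"
        assert [a.charge for a in v.atoms] == [a.charge for a in toy_structure.atoms]

    def test_atrophy_restore_composition(self, toy_structure, keys):
        spec = ChargeVariantSpec(atrophy=True, keep_list=[keys["LYS"]],
                                 restore_list=[keys["ASP"]])
        v, label = build_variant(toy_structure, spec)
        manual = restore_residues(
            apply_atrophy(toy_structure, [keys["LYS"]]), toy_structure, [keys["ASP"]]
        )
        assert [a.charge for a in v.atoms] == [a.charge for a in manual.atoms]
        assert label == "Velec(D1)"  # Asp sits at position 1 in the toy

    def test_nonzero_charges_exactly_on_recipe_set(self, toy_structure, keys):
        spec = ChargeVariantSpec(
            atrophy=True, keep_list=[keys["LYS"]], restore_list=[keys["ASP"], "waters"]
        )
        v, _ = build_variant(toy_structure, spec)
        allowed = {keys["LYS"], keys["ASP"]}
        for a in v.atoms:
            if a.charge != 0.0:
                assert (
                    a.residue_key in allowed
                    or a.group_kind in ("substrate", "water")
                )

    def test_yaml_round_trip(self, keys):
        spec = ChargeVariantSpec(
            atrophy=True,
            keep_list=[keys["LYS"]],
            restore_list=[keys["ASP"], "waters"],
            lambda_map={keys["GLU"]: 0.8},
        )
        again = ChargeVariantSpec.from_yaml(spec.to_yaml())
        assert again == spec

    def test_conflicting_mutation_and_keep_rejected(self, keys):
        with pytest.raises(ValueError, match="keep_list and mutations"):
            ChargeVariantSpec(
                atrophy=True, keep_list=[keys["ASP"]], mutations={keys["ASP"]: "ALA"}
            )
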