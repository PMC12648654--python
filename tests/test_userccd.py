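"""User-CCD component building: bonds, charges, covalent merge, CIF, jobs."""

import json
import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccd2md import fixtures
from ccd2md.errors import (MultiplicityError, UsageError, ValidationError)
from ccd2md.structure_io import Atom, Structure
from ccd2md.userccd import (AF3Job, ComponentAtom, ComponentDef,
                            CovalentPart, Defaults, assign_formal_charges,
                            build_job, emit_cif, extract_component,
                            infer_bonds, merge_covalent, parse_cif,
                            parse_protein_args, round_formal_charge)


def brute_force_bonds(atoms, cutoff):
    """Independent all-pairs double loop (the oracle)."""
    edges = set()
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if math.dist(atoms[i][1], atoms[j][1]) <= cutoff:
                edges.add(frozenset({atoms[i][0], atoms[j][0]}))
    return edges


class TestInferBonds:
    def test_pair_within_cutoff_bonds(self):
        g = infer_bonds([("A", (0, 0, 0)), ("B", (1.0, 0, 0))], 1.4)
        assert g.edge_set() == {frozenset({"A", "B"})}

    def test_pair_beyond_cutoff_does_not(self):
        g = infer_bonds([("A", (0, 0, 0)), ("B", (2.0, 0, 0))], 1.4)
        assert g.edge_set() == set()

    def test_boundary_is_closed(self):
        g = infer_bonds([("A", (0, 0, 0)), ("B", (1.4, 0, 0))], 1.4)
        assert g.edge_set() == {frozenset({"A", "B"})}

    @pytest.mark.parametrize("seed", range(12))
    def test_random_cloud_equals_brute_force(self, seed):
        atoms = fixtures.make_cloud(30, seed, box=5.0)
        g = infer_bonds(atoms, 1.4)
        assert g.edge_set() == brute_force_bonds(atoms, 1.4)

    @given(seed=st.integers(0, 10_000), n=st.integers(1, 60))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_oracle_equivalence_property(self, seed, n):
        atoms = fixtures.make_cloud(n, seed, box=6.0)
        assert infer_bonds(atoms, 1.4).edge_set() == \
            brute_force_bonds(atoms, 1.4)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        atoms = fixtures.make_cloud(40, 3, box=6.0)
        # a random rotation (QR of a Gaussian matrix) plus translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(size=3) * 10
        moved = [(name, tuple((q @ np.array(xyz) + t).tolist()))
                 for name, xyz in atoms]
        assert infer_bonds(atoms, 1.4).edge_set() == \
            infer_bonds(moved, 1.4).edge_set()


class TestFormalCharges:
    @pytest.mark.parametrize("q,expect", [
        (0.0, 0), (-0.98, -1), (0.8, 1), (0.74, 0), (0.75, 1), (-0.5, 0),
        (1.6, 2), (1.4, 1),
    ])
    def test_examples(self, q, expect):
        assert round_formal_charge(q, 0.75) == expect

    def test_sweep_matches_oracle_formula(self):
        def oracle(q, cutoff):
            n = int(math.copysign(math.floor(abs(q) + 0.5), q))
            return n if abs(q) >= cutoff * max(abs(n), 1) else 0

        for i in range(0, 101):
            q = i / 100.0
            for cutoff in (0.5, 0.75, 0.9):
                assert round_formal_charge(q, cutoff) == oracle(q, cutoff)
                assert round_formal_charge(-q, cutoff) == oracle(-q, cutoff)

    def test_assign_validates_cutoff(self):
        with pytest.raises(ValueError):
            assign_formal_charges({}, 0.0)


def _chain3(res="LIG"):
    atoms = [Atom(serial=i + 1, name=f"C{i+1}", element="C", res_name=res,
                  res_seq=1, chain_id="", xyz=(float(i), 0.0, 0.0),
                  record_kind="HETATM") for i in range(3)]
    return Structure(atoms=atoms)


class TestExtractComponent:
    def test_proximity_bonds_for_chained_atoms(self):
        comp = extract_component(_chain3(), "LIG")
        assert comp.bonds.edge_set() == {frozenset({"C1", "C2"}),
                                         frozenset({"C2", "C3"})}

    def test_supplied_topology_overrides_proximity(self):
        from ccd2md.topology_io import BondGraph

        g = BondGraph(nodes=["C1", "C2", "C3"])
        g.add_edge("C1", "C3")
        comp = extract_component(_chain3(), "LIG", topo=(g, {}))
        assert comp.bonds.edge_set() == {frozenset({"C1", "C3"})}

    def test_charges_round_at_default_cutoff(self):
        from ccd2md.topology_io import BondGraph

        g = BondGraph(nodes=["C1", "C2", "C3"])
        comp = extract_component(
            _chain3(), "LIG", topo=(g, {"C1": -0.8, "C2": 0.8, "C3": 0.0}))
        assert [a.formal_charge for a in comp.atoms] == [-1, 1, 0]

    def test_multiplicity_errors(self):
        s = _chain3()
        with pytest.raises(MultiplicityError):
            extract_component(s, "NOPE")
        doubled = Structure(atoms=s.atoms + [
            replace(a, res_seq=2) for a in s.atoms])
        with pytest.raises(MultiplicityError):
            extract_component(doubled, "LIG")

    def test_hydrogens_stripped_unless_flagged(self):
        s = _chain3()
        s.atoms.append(Atom(serial=4, name="H1", element="H", res_name="LIG",
                            res_seq=1, chain_id="", xyz=(0.5, 0.5, 0.0)))
        heavy = extract_component(s, "LIG")
        assert all(a.element != "H" for a in heavy.atoms)
        full = extract_component(s, "LIG", include_hydrogens=True)
        assert any(a.element == "H" for a in full.atoms)
        assert len(full.bonds) >= len(heavy.bonds)


class TestMergeCovalent:
    def test_single_part_equals_extract(self):
        merged = merge_covalent([CovalentPart(_chain3())], "LIG")
        solo = extract_component(_chain3(), "LIG")
        assert merged.atoms == solo.atoms
        assert merged.bonds.edge_set() == solo.bonds.edge_set()

    def test_first_instance_coordinates_win(self):
        first = _chain3("CPX")
        displaced = Structure(atoms=[
            replace(a, xyz=(a.xyz[0] + 9.0, 5.0, 5.0)) for a in first.atoms])
        comp = merge_covalent([CovalentPart(first), CovalentPart(displaced)],
                              "CPX2")
        coords = {a.name: a.ideal_xyz for a in comp.atoms}
        for name in ("C1", "C2", "C3"):
            assert coords[f"{name}_2"] == coords[name]

    def test_aba_chain_atom_count_and_unique_names(self):
        a = _chain3("AAA")
        b = Structure(atoms=[
            replace(at, res_name="BBB", xyz=(at.xyz[0] + 10, 0.0, 0.0))
            for at in _chain3().atoms] + [
            Atom(serial=4, name="O4", element="O", res_name="BBB", res_seq=1,
                 chain_id="", xyz=(13.0, 0.0, 0.0), record_kind="HETATM")])
        a2 = Structure(atoms=[
            replace(at, xyz=(at.xyz[0] + 20, 0.0, 0.0)) for at in a.atoms])
        comp = merge_covalent(
            [CovalentPart(a), CovalentPart(b), CovalentPart(a2)], "ABA")
        names = [at.name for at in comp.atoms]
        assert len(names) == 2 * 3 + 4
        assert len(set(names)) == len(names)
        # oracle: manual union with the suffix rule
        assert names[:3] == ["C1", "C2", "C3"]
        assert set(names[3:7]) == {"C1_2", "C2_2", "C3_2", "O4"}

    def test_rename_rejected(self):
        with pytest.raises(UsageError):
            merge_covalent([CovalentPart(_chain3())], "LIG",
                           rename_requested=True)

    def test_mixed_hydrogen_content_is_inconsistent(self):
        plain = _chain3("AAA")
        with_h = Structure(atoms=_chain3("BBB").atoms + [
            Atom(serial=9, name="H9", element="H", res_name="BBB", res_seq=1,
                 chain_id="", xyz=(50.0, 0.0, 0.0))])
        with pytest.raises(ValidationError, match="hydrogen"):
            merge_covalent([CovalentPart(plain), CovalentPart(with_h)], "AB")
        # keeping hydrogens resolves the inconsistency
        comp = merge_covalent([CovalentPart(plain), CovalentPart(with_h)],
                              "AB", include_hydrogens=True)
        assert any(a.element == "H" for a in comp.atoms)


class TestCifRoundTrip:
    def test_one_atom_component(self):
        from ccd2md.topology_io import BondGraph

        comp = ComponentDef("ONE", (ComponentAtom("C1", "C", (0.0, 0.0, 0.0)),),
                            BondGraph(nodes=["C1"]))
        text = emit_cif(comp)
        assert "_chem_comp_bond" not in text
        assert parse_cif(text) == comp

    def test_three_atom_round_trip_field_by_field(self):
        comp = extract_component(_chain3(), "LIG")
        again = parse_cif(emit_cif(comp))
        assert again.comp_id == comp.comp_id
        assert again.atoms == comp.atoms
        assert again.bonds.edge_set() == comp.bonds.edge_set()

    def test_emit_parse_emit_byte_stable(self, ligands):
        for lig in ligands.values():
            comp = extract_component(lig.ff_structure,
                                     lig.spec.name_ff)
            text = emit_cif(comp)
            assert emit_cif(parse_cif(text)) == text

    def test_negative_charge_transcribed(self):
        from ccd2md.topology_io import BondGraph

        comp = ComponentDef(
            "NEG", (ComponentAtom("O1", "O", (0.0, 0.0, 0.0), -1),),
            BondGraph(nodes=["O1"]))
        assert "NEG O1 O -1" in emit_cif(comp)

    def test_whitespace_comp_id_rejected(self):
        from ccd2md.topology_io import BondGraph

        with pytest.raises(ValidationError):
            ComponentDef("BAD ID", (), BondGraph())


class TestJob:
    def test_defaults_match_zero_configuration(self):
        d = Defaults()
        assert (d.charge_cutoff, d.bond_cutoff) == (0.75, 1.4)
        assert d.json_name == "output.json"
        assert (d.dialect, d.af_version) == ("alphafold3", 2)
        assert d.title == "pos2cif_system"
        assert d.seeds == (1,)

    def test_job_with_defaults(self):
        comp = extract_component(_chain3(), "LIG")
        job = build_job([comp], [("ACDEF", 1)])
        doc = job.to_dict()
        assert doc["modelSeeds"] == [1]
        assert doc["version"] == 2
        assert doc["dialect"] == "alphafold3"
        assert doc["name"] == "pos2cif_system"
        assert doc["sequences"][0]["protein"]["sequence"] == "ACDEF"
        assert doc["sequences"][1]["ligand"]["ccdCodes"] == ["LIG"]
        assert "data_LIG" in doc["userCCD"]
        assert json.loads(job.to_json()) == doc

    def test_ligand_ids_must_appear_in_userccd(self):
        with pytest.raises(ValidationError):
            AF3Job(name="x", dialect="alphafold3", version=2,
                   model_seeds=[1], proteins=[], ligand_ids=["GHOST"],
                   user_ccd="")

    def test_seeds_must_be_nonempty(self):
        with pytest.raises(ValidationError):
            AF3Job(name="x", dialect="alphafold3", version=2,
                   model_seeds=[], proteins=[], ligand_ids=[], user_ccd="")


class TestProteinGrammar:
    def test_single_fasta_followed_by_n(self):
        assert parse_protein_args(["ACDEF", "3"]) == [("ACDEF", 3)]

    def test_repeated_fasta_counts(self):
        assert parse_protein_args(["ACDEF", "ACDEF"]) == [("ACDEF", 2)]

    def test_combination(self):
        assert parse_protein_args(["ACDEF", "2", "ACDEF"]) == [("ACDEF", 3)]
        assert parse_protein_args(["ACD", "GGG", "2"]) == \
            [("ACD", 1), ("GGG", 2)]

    def test_numeral_without_sequence_is_error(self):
        with pytest.raises(UsageError):
            parse_protein_args(["3"])

    def test_zero_copies_is_error(self):
        with pytest.raises(UsageError):
            parse_protein_args(["ACDEF", "0"])

    def test_invalid_letters_rejected(self):
        with pytest.raises(UsageError):
            parse_protein_args(["ACDB5"])
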