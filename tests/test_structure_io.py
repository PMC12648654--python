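"""Structure parsing, writing and normalisation."""

import math

import pytest

from ccd2md import fixtures
from ccd2md.errors import ParseError, UnsupportedFormatError
from ccd2md.structure_io import (Atom, ChainPolicy, Structure, infer_element,
                                 read_structure, reorder_chains,
                                 strip_hydrogens, write_structure)

FIVE_ATOM_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1      12.560   6.071  -6.342  1.00  0.00           C
HETATM    3  O1  LIG B   2       1.500  -2.250   0.000  1.00  0.00           O
HETATM    4 1HB  LIG B   2       2.000  -2.250   0.000  1.00  0.00
HETATM    5 HG   HGX B   3       3.000   0.000   1.250  1.00  0.00
"""


def naive_pdb_parse(text):
    """Independent column-slicing reference parser (the test oracle)."""
    rows = []
    for line in text.splitlines():
        if line[:6].strip() not in ("ATOM", "HETATM"):
            continue
        rows.append({
            "kind": line[:6].strip(),
            "serial": int(line[6:11]),
            "name": line[12:16].strip(),
            "res_name": line[17:21].strip(),
            "chain": line[21].strip(),
            "res_seq": int(line[22:26]),
            "xyz": (float(line[30:38]), float(line[38:46]),
                    float(line[46:54])),
        })
    return rows


def test_pdb_fields_match_reference_parser():
    s = read_structure(FIVE_ATOM_PDB, "PDB")
    ref = naive_pdb_parse(FIVE_ATOM_PDB)
    assert len(s.atoms) == len(ref) == 5
    for atom, row in zip(s.atoms, ref):
        assert atom.record_kind == row["kind"]
        assert atom.serial == row["serial"]
        assert atom.name == row["name"]
        assert atom.res_name == row["res_name"]
        assert atom.chain_id == row["chain"]
        assert atom.res_seq == row["res_seq"]
        assert atom.xyz == row["xyz"]


def test_empty_atom_section_parses_to_zero_atoms():
    assert len(read_structure("END\n", "PDB").atoms) == 0
    assert len(read_structure("title\n    0\n   0.0 0.0 0.0\n", "GRO").atoms) == 0


def test_gro_coordinates_convert_nm_to_angstrom():
    gro = "t\n    1\n    1LIG    C1    1   0.100   0.200   0.300\n   0 0 0\n"
    (atom,) = read_structure(gro, "GRO").atoms
    assert atom.xyz == pytest.approx((1.0, 2.0, 3.0), abs=1e-9)


def test_unknown_format_rejected():
    with pytest.raises(UnsupportedFormatError):
        read_structure("", "XYZ")


def test_malformed_pdb_line_reports_line_number():
    bad = "ATOM      1  N   GLY A   1      xx.xxx   6.134  -6.504\n"
    with pytest.raises(ParseError, match="line 1"):
        read_structure(bad, "PDB")


def test_first_model_only():
    text = ("MODEL     1\n" + FIVE_ATOM_PDB + "ENDMDL\nMODEL     2\n"
            + FIVE_ATOM_PDB + "ENDMDL\n")
    assert len(read_structure(text, "PDB").atoms) == 5


@pytest.mark.parametrize("name,element", [
    ("1HB", "H"), ("HB2", "H"), ("HG", "Hg"), ("HE21", "He"), ("CA", "C"),
    ("N", "N"), ("2OP", "O"), ("P", "P"),
])
def test_element_inference_rule(name, element):
    assert infer_element(name) == element


def test_strip_hydrogens_water_and_named_hydrogens():
    s = read_structure(FIVE_ATOM_PDB, "PDB")
    stripped = strip_hydrogens(s)
    # 1HB strips (hydrogen name), HG in residue HGX is mercury and stays
    assert [a.name for a in stripped.atoms] == ["N", "CA", "O1", "HG"]
    assert strip_hydrogens(stripped).atoms == stripped.atoms  # idempotent


def test_strip_hydrogens_order_preserved(ligands):
    from dataclasses import replace
    base = ligands["CHL1"].ff_structure
    atoms = []
    for i, a in enumerate(base.atoms):
        atoms.append(a)
        atoms.append(replace(a, name=f"H{i+1}", element="H"))
    padded = Structure(atoms=atoms)
    assert [a.name for a in strip_hydrogens(padded).atoms] == \
        [a.name for a in base.atoms]


def _atom(chain, seq=1, name="C1"):
    return Atom(serial=1, name=name, element="C", res_name="LIG",
                res_seq=seq, chain_id=chain, xyz=(0.0, 0.0, 0.0))


def test_reorder_chains_empty_chain_last():
    s = Structure(atoms=[_atom("B"), _atom(""), _atom("A")])
    out = reorder_chains(s, ChainPolicy())
    assert [a.chain_id for a in out.atoms] == ["A", "B", ""]


def test_reorder_chains_matches_oracle_stable_sort():
    import random

    rng = random.Random(7)
    chains = [rng.choice("ABCD ") .strip() for _ in range(40)]
    atoms = [_atom(c, seq=i) for i, c in enumerate(chains)]
    out = reorder_chains(Structure(atoms=atoms))
    oracle = sorted(atoms, key=lambda a: (a.chain_id == "", a.chain_id))
    assert out.atoms == oracle
    # single chain: unchanged
    single = Structure(atoms=[_atom("A", i) for i in range(5)])
    assert reorder_chains(single).atoms == single.atoms


@pytest.mark.parametrize("fmt,tol", [("PDB", 1e-3), ("GRO", 1e-2)])
def test_write_read_round_trip(chl, fmt, tol):
    s = chl.ff_structure
    text = write_structure(s, fmt)
    back = read_structure(text, fmt)
    assert [a.name for a in back.atoms] == [a.name for a in s.atoms]
    assert [a.res_name for a in back.atoms] == [a.res_name for a in s.atoms]
    for a, b in zip(back.atoms, s.atoms):
        assert a.xyz == pytest.approx(b.xyz, abs=tol)


@pytest.mark.parametrize("fmt", ["PDB", "GRO"])
@pytest.mark.parametrize("seed", range(6))
def test_second_write_is_byte_stable(seed, fmt):
    from conftest import varied_spec

    lig = fixtures.make_ligand(varied_spec(seed))
    first = write_structure(lig.ccd_structure, fmt)
    second = write_structure(read_structure(first, fmt), fmt)
    assert first == second


def test_mmcif_label_with_auth_fallback():
    cif = """\
data_x
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.auth_atom_id
_atom_site.label_comp_id
_atom_site.auth_asym_id
_atom_site.auth_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
HETATM 1 C C1 LIG A 7 1.0 2.0 3.0
"""
    (atom,) = read_structure(cif, "CIF").atoms
    assert atom.name == "C1" and atom.res_name == "LIG"
    assert atom.chain_id == "A" and atom.res_seq == 7
    assert atom.xyz == (1.0, 2.0, 3.0)


def test_cross_format_equivalence(ligands):
    for lig in ligands.values():
        fm = fixtures.emit_formats(lig)
        parsed = {f: read_structure(fm[f], f) for f in ("PDB", "GRO", "CIF")}
        ref = parsed["PDB"]
        for other in (parsed["GRO"], parsed["CIF"]):
            assert [a.name for a in other.atoms] == [a.name for a in ref.atoms]
            assert [a.res_name for a in other.atoms] == \
                [a.res_name for a in ref.atoms]
            for a, b in zip(other.atoms, ref.atoms):
                assert math.dist(a.xyz, b.xyz) < 0.01
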