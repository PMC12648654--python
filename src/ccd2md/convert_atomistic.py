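"""Rename and reorder ligand atoms between CCD and force-field naming.

The converter walks every non-protein residue of a structure; residues
whose name matches a database code in the requested direction are renamed,
their atoms renamed through the ligand's atom map and emitted in the map's
output order, with coordinates untouched.  Ligands not found in the
database pass through unchanged.  Chains are processed alphabetically with
empty chains handled last; by default ligands keep their chain and residue
numbering continues from any preceding protein, while the separate-chain
option moves all converted ligands onto a fresh chain numbered from 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import mapping_db
from .errors import ChainAllocationError, IncompleteLigandError
from .mapping_db import MappingDatabase
from .structure_io import (PROTEIN_RESIDUES, Atom, Structure, iter_residues,
                           reorder_chains, strip_hydrogens)

CCD_TO_FF = "ccd2ff"
FF_TO_CCD = "ff2ccd"


@dataclass
class ConversionReport:
    converted: list[tuple[str, str, str, int]] = field(default_factory=list)
    passed_through: list[str] = field(default_factory=list)
    hydrogens_removed: int = 0


def _resolve(db: MappingDatabase, res_name: str, direction: str):
    """Return ``(new_res_name, atom_map)`` for a convertible residue, else None."""
    if direction == CCD_TO_FF:
        entry = mapping_db.lookup_by_ccd(db, res_name)
        if entry is None or entry.ff_name not in db.atom_maps:
            return None
        return entry.ff_name, db.atom_maps[entry.ff_name]
    if direction == FF_TO_CCD:
        entry = mapping_db.lookup_by_ff(db, res_name)
        if entry is None or entry.ccd_code is None:
            return None
        if entry.ff_name not in db.atom_maps:
            return None
        return entry.ccd_code, db.atom_maps[entry.ff_name].inverted()
    raise ValueError(f"unknown direction {direction!r}")


def convert_ligands(s: Structure, db: MappingDatabase, direction: str,
                    ligand_separate_chain: bool = False
                    ) -> tuple[Structure, ConversionReport]:
    """Convert every matching ligand residue of ``s`` in the given direction."""
    report = ConversionReport()
    n_before = len(s.atoms)
    s = strip_hydrogens(s)
    report.hydrogens_removed = n_before - len(s.atoms)

    out_atoms: list[Atom] = []
    ligand_flags: list[bool] = []  # per output atom: converted ligand?
    for (chain, res_seq, res_name), atoms in iter_residues(s):
        if res_name in PROTEIN_RESIDUES:
            out_atoms.extend(atoms)
            ligand_flags.extend([False] * len(atoms))
            continue
        resolved = _resolve(db, res_name, direction)
        if resolved is None:
            report.passed_through.append(f"{chain or '-'}/{res_seq}/{res_name}")
            out_atoms.extend(atoms)
            ligand_flags.extend([False] * len(atoms))
            continue
        new_name, amap = resolved
        have = {a.name for a in atoms}
        want = amap.source_names
        if have != want:
            raise IncompleteLigandError(res_name, missing=want - have,
                                        extra=have - want)
        by_name = {a.name: a for a in atoms}
        for src, tgt in amap.entries:
            a = by_name[src]
            out_atoms.append(replace(a, name=tgt, res_name=new_name,
                                     record_kind="HETATM"))
        ligand_flags.append(True)
        ligand_flags.extend([True] * (len(atoms) - 1))
        report.converted.append((res_name, new_name, chain, res_seq))

    out = replace(s, atoms=out_atoms)
    out, ligand_flags = _reorder_with_flags(out, ligand_flags)
    if ligand_separate_chain:
        out = _move_ligands_to_new_chain(out, ligand_flags)
    else:
        out = _continue_numbering(out, ligand_flags)
    return out, report


def _reorder_with_flags(s: Structure, flags: list[bool]
                        ) -> tuple[Structure, list[bool]]:
    tagged = replace(s, atoms=[replace(a, serial=i) for i, a in
                               enumerate(s.atoms)])
    ordered = reorder_chains(tagged)
    new_flags = [flags[a.serial] for a in ordered.atoms]
    atoms = [replace(a, serial=i + 1) for i, a in enumerate(ordered.atoms)]
    return replace(ordered, atoms=atoms), new_flags


def _is_ligand_atom(a: Atom) -> bool:
    return a.res_name not in PROTEIN_RESIDUES


def _continue_numbering(s: Structure, flags: list[bool]) -> Structure:
    """Renumber non-protein residues to continue from the preceding protein."""
    protein_max = max((a.res_seq for a in s.atoms
                       if not _is_ligand_atom(a)), default=None)
    if protein_max is None:
        return s
    atoms: list[Atom] = []
    next_seq = protein_max
    last_key = None
    for a in s.atoms:
        if not _is_ligand_atom(a):
            atoms.append(a)
            continue
        key = (a.chain_id, a.res_seq, a.res_name)
        if key != last_key:
            next_seq += 1
            last_key = key
        atoms.append(replace(a, res_seq=next_seq))
    return replace(s, atoms=atoms)


def assign_ligand_chain(s: Structure, enabled: bool) -> Structure:
    """Move all ligand residues onto one fresh chain, numbered from 1."""
    if not enabled:
        return s
    flags = [_is_ligand_atom(a) for a in s.atoms]
    return _move_ligands_to_new_chain(s, flags)


def _move_ligands_to_new_chain(s: Structure, flags: list[bool]) -> Structure:
    if not any(flags):
        return s
    used = {a.chain_id for a, f in zip(s.atoms, flags) if not f}
    new_chain = next((c for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                      if c not in used), None)
    if new_chain is None:
        raise ChainAllocationError("all 26 chain letters are in use")
    atoms: list[Atom] = []
    seq = 0
    last_key = None
    for a, is_lig in zip(s.atoms, flags):
        if not is_lig:
            atoms.append(a)
            continue
        key = (a.chain_id, a.res_seq, a.res_name)
        if key != last_key:
            seq += 1
            last_key = key
        atoms.append(replace(a, chain_id=new_chain, res_seq=seq))
    return replace(s, atoms=atoms)
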