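"""Map atomistic ligands to Martini-style coarse-grained beads.

Each bead is placed at the centre of mass of its contributing heavy atoms
(hydrogens, absent from co-folding outputs, are excluded; if present in
the input they are ignored rather than rejected).  Masses are standard
atomic weights by element.  Coarse-grained ligands are emitted without
chain information, with residue numbering continuing from the protein.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import gemmi
import numpy as np

from .errors import IncompleteLigandError, UsageError
from .mapping_db import BeadMap
from .structure_io import Atom, Structure

MassTable = dict[str, float]


def standard_mass(element: str, masses: MassTable | None = None) -> float:
    """Standard atomic weight (u) of an element, via a table or gemmi."""
    if masses and element in masses:
        return masses[element]
    w = gemmi.Element(element).weight
    if not w or w <= 0:
        raise ValueError(f"no standard atomic mass for element {element!r}")
    return w


@dataclass(frozen=True)
class Bead:
    """A coarse-grained bead; carries no chain identifier."""

    name: str
    xyz: tuple[float, float, float]
    res_name: str
    res_seq: int
    mass: float = 0.0


def cg_map_ligand(ligand_atoms: list[Atom], bm: BeadMap, cg_name: str,
                  res_seq: int = 1,
                  masses: MassTable | None = None) -> list[Bead]:
    """Place each bead of ``bm`` at the centre of mass of its heavy atoms."""
    heavy = {a.name: a for a in ligand_atoms if not a.is_hydrogen}
    beads: list[Bead] = []
    for bead_name, members in bm.beads:
        missing = [m for m in members if m not in heavy]
        if missing:
            raise IncompleteLigandError(bm.ligand, missing=missing)
        w = np.array([standard_mass(heavy[m].element, masses)
                      for m in members])
        coords = np.array([heavy[m].xyz for m in members])
        com = (w[:, None] * coords).sum(axis=0) / w.sum()
        beads.append(Bead(name=bead_name, xyz=tuple(com.tolist()),
                          res_name=cg_name, res_seq=res_seq,
                          mass=float(w.sum())))
    return beads


def assemble_cg_system(protein_cg: Structure,
                       ligand_beads: list[list[Bead]]) -> Structure:
    """Concatenate protein beads and ligand beads into one structure.

    Protein bead order is preserved; ligand beads follow with blank chains
    and residue numbering continuing from the protein.
    """
    atoms = list(protein_cg.atoms)
    next_seq = max((a.res_seq for a in atoms), default=0)
    serial = len(atoms)
    for beads in ligand_beads:
        next_seq += 1
        for b in beads:
            serial += 1
            atoms.append(Atom(
                serial=serial, name=b.name, element="",
                res_name=b.res_name, res_seq=next_seq, chain_id="",
                xyz=b.xyz, record_kind="HETATM"))
    return replace(protein_cg, atoms=atoms)


def plan_martinize_invocation(mode: str | None = None,
                              extra_args: list[str] | None = None,
                              ptm_present: bool = False,
                              membrane: bool = False) -> list[str]:
    """Build the argument list for the external protein coarse-grainer.

    Secondary-structure biasing defaults to an elastic network when neither
    elastic nor Go̅ mode is requested.  A Go̅ network is incompatible with
    membrane embedding.  When post-translational modifications are present,
    ``-resid input`` is appended unless the caller supplied a ``-resid``
    choice themselves.
    """
    extra = list(extra_args or [])
    if mode is None:
        mode = "elastic"
    if mode not in ("elastic", "go"):
        raise UsageError(f"unknown secondary-structure mode {mode!r}")
    if mode == "go" and membrane:
        raise UsageError("Go̅ networks are incompatible with membrane "
                         "embedding")
    args = ["-elastic"] if mode == "elastic" else ["-go"]
    args.extend(extra)
    if ptm_present and "-resid" not in extra:
        args.extend(["-resid", "input"])
    return args
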