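"""Build user-defined CCD chemical components and AlphaFold3 job documents.

A component is assembled from ligand coordinates (PDB/GRO/CRD/MOL2), with
bonds taken from topology files when supplied and otherwise inferred from
interatomic proximity under a hard distance cutoff (default 1.4 Å, closed
at the boundary).  Partial charges, when available, are rounded to formal
integer charges under a cutoff rule (default 0.75 e).  Bond order and
aromaticity are required by AlphaFold3 but not used to generate the model,
so all emitted bonds are single and nonaromatic.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import (MultiplicityError, ParseError, UsageError,
                     ValidationError)
from .structure_io import Structure, iter_residues
from .topology_io import BondGraph, ChargeTable

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class Defaults:
    """Zero-configuration state of the generator; every field is overridable."""

    charge_cutoff: float = 0.75   # e
    bond_cutoff: float = 1.4      # Å
    json_name: str = "output.json"
    dialect: str = "alphafold3"
    af_version: int = 2
    title: str = "pos2cif_system"
    seeds: tuple[int, ...] = (1,)


@dataclass(frozen=True)
class ComponentAtom:
    name: str
    element: str
    ideal_xyz: tuple[float, float, float]
    formal_charge: int = 0


@dataclass(frozen=True)
class ComponentDef:
    """A user-CCD chemical component: single residue, single logical chain."""

    comp_id: str
    atoms: tuple[ComponentAtom, ...]
    bonds: BondGraph
    include_hydrogens: bool = False

    def __post_init__(self):
        if not self.comp_id or any(c.isspace() for c in self.comp_id):
            raise ValidationError(
                f"component id {self.comp_id!r} must be nonempty without "
                f"whitespace")
        names = {a.name for a in self.atoms}
        for a, b in self.bonds.edges:
            if a not in names or b not in names:
                raise ValidationError(
                    f"bond ({a},{b}) endpoint not an atom of {self.comp_id!r}")
        if not self.include_hydrogens:
            hyd = [a.name for a in self.atoms if a.element.upper() == "H"]
            if hyd:
                raise ValidationError(
                    f"{self.comp_id!r}: hydrogens present with "
                    f"include_hydrogens=False: {hyd}")

    def __eq__(self, other):
        if not isinstance(other, ComponentDef):
            return NotImplemented
        return (self.comp_id == other.comp_id and self.atoms == other.atoms
                and self.bonds.edge_set() == other.bonds.edge_set())


def infer_bonds(atoms: list[tuple[str, tuple[float, float, float]]],
                cutoff: float) -> BondGraph:
    """Bond every atom pair whose separation is ≤ ``cutoff`` (Å).

    All inferred bonds are single and nonaromatic.  An unbonded atom is
    legal; a fully disconnected result is logged as a warning.
    """
    if cutoff <= 0:
        raise ValueError("bond cutoff must be positive")
    if not atoms:
        raise ValueError("at least one atom required")
    names = [n for n, _ in atoms]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate atom names in bond inference input")
    graph = BondGraph(nodes=list(names))
    coords = np.asarray([xyz for _, xyz in atoms], dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=-1))
    ii, jj = np.nonzero(np.triu(dist <= cutoff, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        graph.add_edge(names[i], names[j])
    if len(atoms) > 1 and not graph.edges:
        logger.warning("no bonds inferred at cutoff %.3f Å: component is "
                       "fully disconnected", cutoff)
    return graph


def round_formal_charge(q: float, cutoff: float) -> int:
    """Round a partial charge to a formal integer under the cutoff rule.

    With n the nearest integer to q (half away from zero), the formal
    charge is n when |q| ≥ cutoff·max(|n|, 1) and 0 otherwise.
    """
    n = int(math.copysign(math.floor(abs(q) + 0.5), q))
    return n if abs(q) >= cutoff * max(abs(n), 1) else 0


def assign_formal_charges(charges: ChargeTable, cutoff: float
                          ) -> dict[str, int]:
    if not (0 < cutoff <= 1):
        raise ValueError("charge cutoff must lie in (0, 1]")
    return {name: round_formal_charge(q, cutoff) for name, q in charges.items()}


def _single_nonaromatic(graph: BondGraph) -> BondGraph:
    out = BondGraph(nodes=list(graph.nodes))
    for (a, b) in graph.edges:
        out.add_edge(a, b, order="single", aromatic=False)
    return out


def _restrict_graph(graph: BondGraph, names: set[str], comp: str,
                    dropping_h: set[str]) -> BondGraph:
    out = BondGraph(nodes=[n for n in graph.nodes if n in names])
    for (a, b), _ in graph.edges.items():
        if a in dropping_h or b in dropping_h:
            continue
        if a not in names or b not in names:
            raise ValidationError(
                f"topology bond ({a},{b}) does not match the atoms of {comp!r}")
        out.add_edge(a, b)
    return out


def extract_component(s: Structure, ligand_name: str,
                      topo: tuple[BondGraph, ChargeTable] | None = None,
                      defaults: Defaults = Defaults(),
                      include_hydrogens: bool = False,
                      comp_id: str | None = None) -> ComponentDef:
    """Build a ComponentDef from the single copy of ``ligand_name`` in ``s``."""
    copies = [atoms for (_, _, rn), atoms in iter_residues(s)
              if rn == ligand_name]
    if len(copies) != 1:
        raise MultiplicityError(
            f"expected exactly one copy of {ligand_name!r}, found {len(copies)}")
    atoms = copies[0]
    hyd = {a.name for a in atoms if a.is_hydrogen}
    if not include_hydrogens:
        atoms = [a for a in atoms if not a.is_hydrogen]
    if not atoms:
        raise ValidationError(f"ligand {ligand_name!r} has no heavy atoms")
    names = {a.name for a in atoms}
    if len(names) != len(atoms):
        raise ValidationError(f"duplicate atom names in ligand {ligand_name!r}")

    if topo is not None:
        graph, charge_table = topo
        unknown = set(graph.nodes) - names - hyd
        if unknown:
            raise ValidationError(
                f"topology atoms {sorted(unknown)} not present in ligand "
                f"{ligand_name!r}")
        graph = _restrict_graph(graph, names, ligand_name,
                                dropping_h=hyd if not include_hydrogens
                                else set())
        formal = assign_formal_charges(
            {n: q for n, q in charge_table.items() if n in names},
            defaults.charge_cutoff)
    else:
        graph = infer_bonds([(a.name, a.xyz) for a in atoms],
                            defaults.bond_cutoff)
        formal = {}

    comp_atoms = tuple(
        ComponentAtom(name=a.name, element=a.element or "C",
                      ideal_xyz=a.xyz, formal_charge=formal.get(a.name, 0))
        for a in atoms)
    return ComponentDef(comp_id=comp_id or ligand_name, atoms=comp_atoms,
                        bonds=_single_nonaromatic(graph),
                        include_hydrogens=include_hydrogens)


# ---------------------------------------------------------------------------
# covalent multi-part ligands
# ---------------------------------------------------------------------------

@dataclass
class CovalentPart:
    structure: Structure
    graph: BondGraph | None = None
    charges: ChargeTable | None = None

    @property
    def res_name(self) -> str:
        if not self.structure.atoms:
            raise ValidationError("covalent part has no atoms")
        return self.structure.atoms[0].res_name


def merge_covalent(parts: list[CovalentPart], comp_id: str,
                   defaults: Defaults = Defaults(),
                   include_hydrogens: bool = False,
                   rename_requested: bool = False) -> ComponentDef:
    """Merge covalently linked parts into one component.

    Atom names of the second and later instances of a repeated component
    get a numeric suffix (``C1`` → ``C1_2``); for repeated components the
    ideal coordinates come from the first instance.  Inter-part bonds come
    from the supplied topologies or, failing that, from proximity at the
    bond cutoff applied across part boundaries (bond geometry is judged on
    each part's own coordinates).  Covalent ligands cannot be renamed.
    """
    if rename_requested:
        raise UsageError("covalently bonded ligands cannot be renamed "
                         "(-r/--rename)")
    if not parts:
        raise UsageError("no covalent parts given")
    _check_hydrogen_consistency(parts, include_hydrogens)

    instance_count: dict[str, int] = {}
    first_instance: dict[str, dict[str, tuple[float, float, float]]] = {}
    placed: list[tuple[str, str, tuple[float, float, float],
                       tuple[float, float, float], int]] = []
    # (unique name, element, ideal xyz, actual xyz, part index)
    part_graphs: list[BondGraph] = []
    part_renames: list[dict[str, str]] = []
    all_names: set[str] = set()
    for pi, part in enumerate(parts):
        atoms = part.structure.atoms
        hyd = {a.name for a in atoms if a.is_hydrogen}
        if not include_hydrogens:
            atoms = [a for a in atoms if not a.is_hydrogen]
        rn = part.res_name
        inst = instance_count.get(rn, 0) + 1
        instance_count[rn] = inst
        local = {a.name for a in atoms}
        if len(local) != len(atoms):
            raise ValidationError(f"duplicate atom names within part {rn!r}")
        if inst == 1:
            first_instance[rn] = {a.name: a.xyz for a in atoms}
        else:
            ref = first_instance[rn]
            if set(ref) != local:
                raise ValidationError(
                    f"instance {inst} of component {rn!r} has different atoms "
                    f"than the first instance")
        rename: dict[str, str] = {}
        for a in atoms:
            # preferred suffix is the instance ordinal; on a collision with a
            # different part's atom the numeral advances to the next free one
            unique = a.name if inst == 1 else f"{a.name}_{inst}"
            k = max(inst, 1)
            while unique in all_names:
                k += 1
                if k > len(parts) + len(all_names):
                    raise ValidationError(
                        f"unresolvable atom-name collision on {a.name!r}")
                unique = f"{a.name}_{k}"
            rename[a.name] = unique
            all_names.add(unique)
        part_renames.append(rename)
        for a in atoms:
            ideal = a.xyz if inst == 1 else first_instance[rn][a.name]
            placed.append((rename[a.name], a.element or "C", ideal, a.xyz, pi))
        if part.graph is not None:
            g = _restrict_graph(part.graph, local, rn,
                                dropping_h=hyd if not include_hydrogens
                                else set())
            renamed = BondGraph(nodes=[rename[n] for n in g.nodes])
            for (x, y) in g.edges:
                renamed.add_edge(rename[x], rename[y])
            part_graphs.append(renamed)
        else:
            part_graphs.append(
                infer_bonds([(rename[a.name], a.xyz) for a in atoms],
                            defaults.bond_cutoff))

    merged = BondGraph(nodes=[name for name, *_ in placed])
    for g in part_graphs:
        for (x, y) in g.edges:
            merged.add_edge(x, y)
    # inter-part proximity bonds on the parts' own (actual) coordinates
    coords = np.asarray([actual for _, _, _, actual, _ in placed])
    part_of = [pi for *_, pi in placed]
    names = [name for name, *_ in placed]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=-1))
    n = len(placed)
    for i in range(n):
        for j in range(i + 1, n):
            if part_of[i] != part_of[j] and dist[i, j] <= defaults.bond_cutoff:
                merged.add_edge(names[i], names[j])

    comp_atoms = tuple(ComponentAtom(name=name, element=el, ideal_xyz=ideal)
                       for name, el, ideal, _, _ in placed)
    formal = _covalent_charges(parts, part_renames, defaults)
    if formal:
        comp_atoms = tuple(
            ComponentAtom(a.name, a.element, a.ideal_xyz,
                          formal.get(a.name, 0)) for a in comp_atoms)
    return ComponentDef(comp_id=comp_id, atoms=comp_atoms,
                        bonds=_single_nonaromatic(merged),
                        include_hydrogens=include_hydrogens)


def _covalent_charges(parts, part_renames, defaults: Defaults
                      ) -> dict[str, int]:
    per_name: ChargeTable = {}
    for part, rename in zip(parts, part_renames):
        if not part.charges:
            continue
        for atom_name, q in part.charges.items():
            if atom_name in rename:
                per_name[rename[atom_name]] = q
    return assign_formal_charges(per_name, defaults.charge_cutoff)


def _check_hydrogen_consistency(parts: list[CovalentPart],
                                include_hydrogens: bool) -> None:
    if include_hydrogens:
        return
    has_h = [any(a.is_hydrogen for a in p.structure.atoms) for p in parts]
    if any(has_h) and not all(has_h):
        raise ValidationError(
            "inconsistent hydrogen content across covalent input files; "
            "default hydrogen stripping requires consistency (use -H to keep "
            "hydrogens)")


# ---------------------------------------------------------------------------
# CIF emission and parsing
# ---------------------------------------------------------------------------

def emit_cif(c: ComponentDef) -> str:
    """Serialise a component as a PDBx chemical-component block."""
    lines = [
        f"data_{c.comp_id}",
        "#",
        f"_chem_comp.id {c.comp_id}",
        "_chem_comp.type non-polymer",
        "#",
        "loop_",
        "_chem_comp_atom.comp_id",
        "_chem_comp_atom.atom_id",
        "_chem_comp_atom.type_symbol",
        "_chem_comp_atom.charge",
        "_chem_comp_atom.pdbx_model_Cartn_x_ideal",
        "_chem_comp_atom.pdbx_model_Cartn_y_ideal",
        "_chem_comp_atom.pdbx_model_Cartn_z_ideal",
    ]
    for a in c.atoms:
        lines.append(
            f"{c.comp_id} {a.name} {a.element.upper()} {a.formal_charge} "
            f"{a.ideal_xyz[0]:.3f} {a.ideal_xyz[1]:.3f} {a.ideal_xyz[2]:.3f}")
    if c.bonds.edges:
        lines += [
            "#",
            "loop_",
            "_chem_comp_bond.comp_id",
            "_chem_comp_bond.atom_id_1",
            "_chem_comp_bond.atom_id_2",
            "_chem_comp_bond.value_order",
            "_chem_comp_bond.pdbx_aromatic_flag",
        ]
        for (x, y) in sorted(c.bonds.edges):
            lines.append(f"{c.comp_id} {x} {y} SING N")
    lines.append("#")
    return "\n".join(lines) + "\n"


def parse_cif(text: str) -> ComponentDef:
    """Parse a chemical-component block emitted by :func:`emit_cif`."""
    try:
        doc = gemmi.cif.read_string(text)
    except (RuntimeError, ValueError) as e:
        raise ParseError(f"component CIF parse failure: {e}") from None
    block = doc.sole_block()
    comp_id = block.find_value("_chem_comp.id") or block.name
    comp_id = gemmi.cif.as_string(comp_id)
    atom_rows = block.find("_chem_comp_atom.",
                           ["atom_id", "type_symbol", "charge",
                            "pdbx_model_Cartn_x_ideal",
                            "pdbx_model_Cartn_y_ideal",
                            "pdbx_model_Cartn_z_ideal"])
    atoms = []
    for row in atom_rows:
        atoms.append(ComponentAtom(
            name=gemmi.cif.as_string(row[0]),
            element=gemmi.cif.as_string(row[1]),
            formal_charge=int(row[2]),
            ideal_xyz=(float(row[3]), float(row[4]), float(row[5]))))
    graph = BondGraph(nodes=[a.name for a in atoms])
    bond_rows = block.find("_chem_comp_bond.", ["atom_id_1", "atom_id_2"])
    for row in bond_rows:
        graph.add_edge(gemmi.cif.as_string(row[0]),
                       gemmi.cif.as_string(row[1]))
    include_h = any(a.element.upper() == "H" for a in atoms)
    return ComponentDef(comp_id=comp_id, atoms=tuple(atoms), bonds=graph,
                        include_hydrogens=include_h)


# ---------------------------------------------------------------------------
# AlphaFold3 job documents
# ---------------------------------------------------------------------------

@dataclass
class AF3Job:
    name: str
    dialect: str
    version: int
    model_seeds: list[int]
    proteins: list[tuple[str, int]]        # (sequence, copies)
    ligand_ids: list[str]                  # component ids
    user_ccd: str

    def __post_init__(self):
        if not self.model_seeds:
            raise ValidationError("model seeds must be nonempty")
        for cid in self.ligand_ids:
            if cid not in self.user_ccd:
                raise ValidationError(
                    f"ligand {cid!r} missing from the userCCD text")

    def to_dict(self) -> dict:
        chain_ids = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
        sequences = []
        for seq, copies in self.proteins:
            ids = [next(chain_ids) for _ in range(copies)]
            sequences.append({"protein": {
                "id": ids[0] if copies == 1 else ids, "sequence": seq}})
        for cid in self.ligand_ids:
            sequences.append({"ligand": {"id": next(chain_ids),
                                         "ccdCodes": [cid]}})
        return {
            "name": self.name,
            "modelSeeds": list(self.model_seeds),
            "sequences": sequences,
            "dialect": self.dialect,
            "version": self.version,
            "userCCD": self.user_ccd,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def parse_protein_args(tokens: list[str]) -> list[tuple[str, int]]:
    """Resolve the mixed FASTA/numeral protein argument grammar.

    N copies may be given as N sequences, one sequence followed by N, or a
    combination; a numeral sets the copy count of the sequence before it.
    Identical sequences aggregate into one entry.
    """
    raw: list[tuple[str, int]] = []
    for tok in tokens:
        if tok.isdigit():
            n = int(tok)
            if not raw:
                raise UsageError("protein copy count with no preceding sequence")
            if n == 0:
                raise UsageError("protein copy count must be positive")
            seq, _ = raw[-1]
            raw[-1] = (seq, n)
        else:
            seq = tok.upper()
            bad = set(seq) - AMINO_ACIDS
            if bad:
                raise UsageError(
                    f"invalid amino-acid letters {sorted(bad)} in protein "
                    f"sequence")
            raw.append((seq, 1))
    merged: dict[str, int] = {}
    order: list[str] = []
    for seq, n in raw:
        if seq not in merged:
            order.append(seq)
            merged[seq] = 0
        merged[seq] += n
    return [(seq, merged[seq]) for seq in order]


def build_job(components: list[ComponentDef],
              proteins: list[tuple[str, int]] | None = None,
              defaults: Defaults = Defaults(),
              **overrides) -> AF3Job:
    """Assemble an AlphaFold3 job embedding the components' user-CCD text."""
    opts = {
        "title": defaults.title,
        "dialect": defaults.dialect,
        "af_version": defaults.af_version,
        "seeds": list(defaults.seeds),
    }
    unknown = set(overrides) - set(opts)
    if unknown:
        raise UsageError(f"unknown job options {sorted(unknown)}")
    opts.update(overrides)
    user_ccd = "".join(emit_cif(c) for c in components)
    return AF3Job(
        name=opts["title"],
        dialect=opts["dialect"],
        version=int(opts["af_version"]),
        model_seeds=[int(x) for x in opts["seeds"]],
        proteins=list(proteins or []),
        ligand_ids=[c.comp_id for c in components],
        user_ccd=user_ccd,
    )
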