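"""Synthetic ligands, structures, mapping files and topology files.

Every generator here emits mutually consistent artifacts with known ground
truth, so converters, bond inference, charge assignment and bead mapping
are all testable offline.  Geometries are toy shapes (chain, ring,
tetrahedral) built so that the intended bond graph is exactly what a
1.4 Å proximity cutoff recovers: bonded neighbours sit at the specified
bond length (default 1.0 Å) and non-neighbours sit farther than 1.4 Å.
The shapes are not chemically realistic lipids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .mapping_db import (AtomMap, BeadMap, MappingDatabase, format_atom_map,
                         format_bead_map, load_database)
from .structure_io import Atom, Structure, write_mmcif, write_structure
from .topology_io import BondGraph, ChargeTable

#: Element assigned to heavy atom i of a toy ligand (cycled).
ELEMENT_CYCLE = ("C", "C", "O", "N", "C", "P", "C", "O")


@dataclass(frozen=True)
class ToyLigandSpec:
    name_ccd: str
    name_ff: str
    name_cg: str | None = None
    n_heavy: int = 6
    geometry: str = "chain"          # chain | ring | tetrahedral
    bond_length: float = 1.0         # Å
    charges: tuple[float, ...] | None = None   # per heavy atom, FF order
    bead_partition: tuple[tuple[int, ...], ...] | None = None
    category: str = "lipid"
    seed: int = 0

    def __post_init__(self):
        if self.n_heavy < 1:
            raise ValidationError("ligand needs at least one heavy atom")
        if self.geometry == "ring" and self.n_heavy < 3:
            raise ValidationError("a ring needs at least three atoms")
        if self.geometry == "tetrahedral" and not 2 <= self.n_heavy <= 5:
            raise ValidationError("tetrahedral geometry supports 2-5 atoms")
        if self.charges is not None and len(self.charges) != self.n_heavy:
            raise ValidationError("charges list must match n_heavy")
        if self.bead_partition is not None:
            seen = sorted(i for g in self.bead_partition for i in g)
            if seen != list(range(self.n_heavy)):
                raise ValidationError(
                    "bead partition must cover each heavy atom exactly once")


@dataclass
class FixtureLigand:
    """All mutually consistent artifacts for one toy ligand."""

    spec: ToyLigandSpec
    ff_structure: Structure          # FF naming, canonical order
    ccd_structure: Structure         # CCD naming, scrambled (recorded) order
    atom_map: AtomMap
    bead_map: BeadMap
    bond_graph: BondGraph            # ground truth, FF names
    charges: ChargeTable             # FF names
    permutation: tuple[int, ...]     # ccd file position -> FF index


def _coordinates(spec: ToyLigandSpec) -> np.ndarray:
    n, b = spec.n_heavy, spec.bond_length
    if spec.geometry == "chain":
        # zig-zag at 120°: neighbours at b, second neighbours at b*sqrt(3)
        pts = []
        x = y = 0.0
        for i in range(n):
            pts.append((x, y, 0.0))
            x += b * math.cos(math.pi / 6)
            y += b * math.sin(math.pi / 6) * (1 if i % 2 == 0 else -1)
        return np.array(pts)
    if spec.geometry == "ring":
        r = b / (2 * math.sin(math.pi / n))
        return np.array([(r * math.cos(2 * math.pi * i / n),
                          r * math.sin(2 * math.pi * i / n), 0.0)
                         for i in range(n)])
    if spec.geometry == "tetrahedral":
        dirs = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)],
                        dtype=float) / math.sqrt(3)
        pts = [np.zeros(3)] + [b * d for d in dirs[: n - 1]]
        return np.array(pts)
    raise ValidationError(f"unknown geometry {spec.geometry!r}")


def _ground_truth_bonds(spec: ToyLigandSpec, names: list[str]) -> BondGraph:
    g = BondGraph(nodes=list(names))
    n = spec.n_heavy
    if spec.geometry == "chain":
        for i in range(n - 1):
            g.add_edge(names[i], names[i + 1])
    elif spec.geometry == "ring":
        if n == 3:
            for i in range(n):
                for j in range(i + 1, n):
                    g.add_edge(names[i], names[j])
        else:
            for i in range(n):
                g.add_edge(names[i], names[(i + 1) % n])
    else:  # tetrahedral: centre is atom 0
        for i in range(1, n):
            g.add_edge(names[0], names[i])
    return g


def _ff_names(spec: ToyLigandSpec) -> list[str]:
    return [f"{ELEMENT_CYCLE[i % len(ELEMENT_CYCLE)]}{i + 1}"
            for i in range(spec.n_heavy)]


def _ccd_names(spec: ToyLigandSpec) -> list[str]:
    return [f"{ELEMENT_CYCLE[i % len(ELEMENT_CYCLE)]}{i + 1}X"
            for i in range(spec.n_heavy)]


def make_ligand(spec: ToyLigandSpec) -> FixtureLigand:
    """Build the full consistent artifact bundle for one toy ligand."""
    coords = _coordinates(spec)
    ff_names = _ff_names(spec)
    ccd_names = _ccd_names(spec)
    elements = [ELEMENT_CYCLE[i % len(ELEMENT_CYCLE)]
                for i in range(spec.n_heavy)]

    def atoms(names, res_name, order):
        return [Atom(serial=k + 1, name=names[i], element=elements[i],
                     res_name=res_name, res_seq=1, chain_id="",
                     xyz=tuple(coords[i].tolist()), record_kind="HETATM")
                for k, i in enumerate(order)]

    rng = np.random.default_rng(spec.seed)
    perm = tuple(int(p) for p in rng.permutation(spec.n_heavy))
    ff_structure = Structure(atoms=atoms(ff_names, spec.name_ff,
                                         range(spec.n_heavy)),
                             source_format="PDB")
    ccd_structure = Structure(atoms=atoms(ccd_names, spec.name_ccd, perm),
                              source_format="PDB")
    atom_map = AtomMap(
        ligand=spec.name_ff,
        entries=tuple(zip(ccd_names, ff_names)),
        source_order=tuple(ccd_names[i] for i in perm),
    )
    partition = spec.bead_partition or tuple(
        tuple(range(i, min(i + 2, spec.n_heavy)))
        for i in range(0, spec.n_heavy, 2))
    bead_map = BeadMap(
        ligand=spec.name_ff,
        beads=tuple((f"B{k + 1}", tuple(ff_names[i] for i in group))
                    for k, group in enumerate(partition)))
    bond_graph = _ground_truth_bonds(spec, ff_names)
    charges = dict(zip(ff_names, spec.charges)) if spec.charges else \
        {n: 0.0 for n in ff_names}
    return FixtureLigand(spec=spec, ff_structure=ff_structure,
                         ccd_structure=ccd_structure, atom_map=atom_map,
                         bead_map=bead_map, bond_graph=bond_graph,
                         charges=charges, permutation=perm)


# ---------------------------------------------------------------------------
# multi-format emission
# ---------------------------------------------------------------------------

def emit_formats(lig: FixtureLigand, which: str = "ff") -> dict[str, str]:
    """Emit one toy ligand in every supported format.

    ``which`` selects the FF-named canonical copy or the CCD-named copy.
    All coordinate emissions describe the same molecule; the topology
    emissions transcribe the ground-truth bond graph and charges.
    """
    s = lig.ff_structure if which == "ff" else lig.ccd_structure
    res = s.atoms[0].res_name
    name_order = [a.name for a in s.atoms]
    out = {
        "PDB": write_structure(s, "PDB"),
        "GRO": write_structure(s, "GRO"),
        "CIF": write_mmcif(s, block_name=res),
    }
    if which == "ff":
        graph, charges = lig.bond_graph, lig.charges
        out["MOL2"] = _emit_mol2(s, graph, charges, res)
        out["ITP"] = _emit_itp(name_order, graph, charges, res)
        out["RTP"] = _emit_rtp(name_order, graph, charges, res)
    return out


def _emit_mol2(s: Structure, graph: BondGraph, charges: ChargeTable,
               res: str) -> str:
    idx = {a.name: i + 1 for i, a in enumerate(s.atoms)}
    lines = ["@<TRIPOS>MOLECULE", res,
             f"{len(s.atoms)} {len(graph.edges)} 1", "SMALL", "USER_CHARGES",
             "@<TRIPOS>ATOM"]
    for a in s.atoms:
        q = charges.get(a.name, 0.0)
        lines.append(f"{idx[a.name]:>4d} {a.name:<6s} "
                     f"{a.xyz[0]:>9.4f} {a.xyz[1]:>9.4f} {a.xyz[2]:>9.4f} "
                     f"{a.element:<4s} 1 {res:<6s} {q:>8.4f}")
    lines.append("@<TRIPOS>BOND")
    for k, (x, y) in enumerate(sorted(graph.edges), start=1):
        lines.append(f"{k:>4d} {idx[x]:>4d} {idx[y]:>4d} 1")
    return "\n".join(lines) + "\n"


def _emit_itp(names: list[str], graph: BondGraph, charges: ChargeTable,
              res: str) -> str:
    idx = {n: i + 1 for i, n in enumerate(names)}
    lines = ["[ moleculetype ]", f"{res}  3", "", "[ atoms ]",
             ";  nr type resnr residue atom cgnr charge"]
    for n in names:
        lines.append(f"{idx[n]:>5d}  {n:<5s} 1  {res:<6s} {n:<5s} "
                     f"{idx[n]:>4d} {charges.get(n, 0.0):>9.4f}")
    lines += ["", "[ bonds ]", ";  ai   aj"]
    for x, y in sorted(graph.edges):
        lines.append(f"{idx[x]:>5d} {idx[y]:>5d}    1")
    return "\n".join(lines) + "\n"


def _emit_rtp(names: list[str], graph: BondGraph, charges: ChargeTable,
              res: str) -> str:
    lines = [f"[ {res} ]", " [ atoms ]"]
    for i, n in enumerate(names):
        lines.append(f"  {n:<5s} {n:<5s} {charges.get(n, 0.0):>9.4f}  {i}")
    lines.append(" [ bonds ]")
    for x, y in sorted(graph.edges):
        lines.append(f"  {x:<5s} {y:<5s}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# protein scaffolds and assembled systems
# ---------------------------------------------------------------------------

def make_protein(n_residues: int, chain: str = "A",
                 start_seq: int = 1) -> Structure:
    """A toy glycine backbone: N, CA, C, O per residue, residues 3.8 Å apart."""
    atoms = []
    serial = 0
    offsets = {"N": (0.0, 0.0, 0.0), "CA": (1.0, 0.4, 0.0),
               "C": (2.0, 0.0, 0.0), "O": (2.4, -0.9, 0.6)}
    for r in range(n_residues):
        base = np.array([3.8 * r, 0.0, 10.0])
        for name, off in offsets.items():
            serial += 1
            atoms.append(Atom(
                serial=serial, name=name, element=name[0],
                res_name="GLY", res_seq=start_seq + r, chain_id=chain,
                xyz=tuple((base + np.array(off)).tolist())))
    return Structure(atoms=atoms, source_format="PDB")


def make_system(protein_residues: int, ligands: list[FixtureLigand],
                which: str = "ccd", ligand_chain: str = "",
                spacing: float = 25.0) -> Structure:
    """A protein plus translated copies of the given ligands, one residue each."""
    s = make_protein(protein_residues)
    atoms = list(s.atoms)
    for k, lig in enumerate(ligands):
        src = lig.ccd_structure if which == "ccd" else lig.ff_structure
        shift = np.array([spacing * (k + 1), spacing, -spacing])
        for a in src.atoms:
            atoms.append(Atom(
                serial=len(atoms) + 1, name=a.name, element=a.element,
                res_name=a.res_name, res_seq=k + 1, chain_id=ligand_chain,
                xyz=tuple((np.array(a.xyz) + shift).tolist()),
                record_kind="HETATM"))
    return Structure(atoms=atoms, source_format="PDB")


def make_cloud(n: int, seed: int, box: float = 10.0
               ) -> list[tuple[str, tuple[float, float, float]]]:
    """A random atom cloud for bond-inference property tests."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.0, box, size=(n, 3))
    return [(f"A{i + 1}", tuple(p.tolist())) for i, p in enumerate(pts)]


# ---------------------------------------------------------------------------
# the shipped fixture database
# ---------------------------------------------------------------------------

#: Representative subset of the master table: documented CCD/CHARMM/Martini
#: name pairs plus one PTM and one detergent.  Atom contents are toy.
DEFAULT_SPECS = (
    ToyLigandSpec("CLR", "CHL1", "CHL1", n_heavy=8, geometry="chain", seed=11),
    ToyLigandSpec("POV", "POPC", "POPC", n_heavy=10, geometry="chain", seed=12,
                  charges=(0.0, -0.8, 0.0, 0.9, 0.0, -0.3, 0.0, 0.0, 0.0, 0.2)),
    ToyLigandSpec("6OU", "POPE", "POPE", n_heavy=9, geometry="chain", seed=13),
    ToyLigandSpec("PGW", "POPG", "POPG", n_heavy=7, geometry="ring", seed=14),
    ToyLigandSpec("D39", "POPS", "POPS", n_heavy=6, geometry="ring", seed=15),
    ToyLigandSpec("PCF", "DPPC", "DPPC", n_heavy=8, geometry="chain", seed=16),
    ToyLigandSpec("CYP", "CYSP", "CYSP", n_heavy=5, geometry="tetrahedral",
                  category="ptm", seed=17),
    ToyLigandSpec("LMT", "BDDM", None, n_heavy=6, geometry="chain",
                  category="detergent", seed=18),
)


def render_database_files(specs=DEFAULT_SPECS) -> dict[str, str]:
    """Render the master CSV and every mapping file for the given specs."""
    rows = ["ff_name,ccd_code,cg_name,category"]
    files: dict[str, str] = {}
    for spec in specs:
        lig = make_ligand(spec)
        rows.append(f"{spec.name_ff},{spec.name_ccd},"
                    f"{spec.name_cg or ''},{spec.category}")
        files[f"{spec.name_ff}.txt"] = format_atom_map(lig.atom_map)
        if spec.name_cg:
            files[f"{spec.name_ff}_CG.txt"] = format_bead_map(lig.bead_map)
    files["database.csv"] = "\n".join(rows) + "\n"
    return files


def build_default_database(specs=DEFAULT_SPECS) -> MappingDatabase:
    files = render_database_files(specs)
    master = files.pop("database.csv")
    return load_database(master, files)


def default_ligands(specs=DEFAULT_SPECS) -> dict[str, FixtureLigand]:
    return {spec.name_ff: make_ligand(spec) for spec in specs}
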