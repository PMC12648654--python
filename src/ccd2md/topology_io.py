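"""Extract bonding and partial-charge information from topology files.

Supported formats: GROMACS ITP (``[ atoms ]``/``[ bonds ]``), CHARMM RTF
and GROMACS RTP residue topologies, Tripos MOL2 and CHARMM CRD.  Only
bonds and per-atom partial charges are consumed; angles, dihedrals and
force-field parameters are ignored — the user-CCD generator needs
connectivity and formal charge only.  CRD files contribute coordinates
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import NotFoundError, ParseError, UsageError, ValidationError
from .structure_io import Atom, Structure, infer_element

ChargeTable = dict[str, float]


@dataclass
class BondGraph:
    """Undirected bond graph over atom names.

    Edges are stored under a sorted name pair; each carries a bond-order
    tag (default ``single``) and an aromaticity flag (default False).
    """

    nodes: list[str] = field(default_factory=list)
    edges: dict[tuple[str, str], tuple[str, bool]] = field(default_factory=dict)

    def add_node(self, name: str) -> None:
        if name not in self.nodes:
            self.nodes.append(name)

    def add_edge(self, a: str, b: str, order: str = "single",
                 aromatic: bool = False) -> None:
        if a == b:
            raise ValidationError(f"self-loop bond on atom {a!r}")
        for end in (a, b):
            if end not in self.nodes:
                raise ValidationError(f"bond references undeclared atom {end!r}")
        self.edges[self.key(a, b)] = (order, aromatic)

    @staticmethod
    def key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def has_edge(self, a: str, b: str) -> bool:
        return self.key(a, b) in self.edges

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset(k) for k in self.edges}

    def __len__(self) -> int:
        return len(self.edges)


_MOL2_ORDERS = {"1": ("single", False), "2": ("double", False),
                "3": ("triple", False), "am": ("single", False),
                "ar": ("single", True), "du": ("single", False),
                "un": ("single", False), "nc": ("single", False)}


def read_topology(source: str, fmt: str, residue: str | None = None
                  ) -> tuple[BondGraph, ChargeTable]:
    """Parse bonds and charges from ITP, RTF, RTP or MOL2 content.

    ``residue`` selects one residue from a multi-residue RTF/RTP file; when
    omitted the file must define exactly one residue.
    """
    fmt = fmt.upper().lstrip(".")
    if fmt == "ITP":
        return _read_itp(source)
    if fmt == "RTP":
        return _read_rtp(source, residue)
    if fmt == "RTF":
        return _read_rtf(source, residue)
    if fmt == "MOL2":
        _, graph, charges = read_mol2(source)
        return graph, charges
    raise ParseError(f"unsupported topology format: {fmt!r}")


def _strip_comment(line: str, chars: str = ";#") -> str:
    for c in chars:
        idx = line.find(c)
        if idx >= 0:
            line = line[:idx]
    return line.rstrip()


def _read_itp(text: str) -> tuple[BondGraph, ChargeTable]:
    section = None
    by_index: dict[int, str] = {}
    graph = BondGraph()
    charges: ChargeTable = {}
    pending: list[tuple[int, int]] = []
    for raw in text.splitlines():
        line = _strip_comment(raw, ";").strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] \t").lower()
            continue
        parts = line.split()
        if section == "atoms":
            # nr type resnr residue atom cgnr charge [mass]
            if len(parts) < 5:
                raise ParseError(f"ITP atoms line too short: {raw!r}")
            idx = int(parts[0])
            name = parts[4]
            if idx in by_index:
                raise ValidationError(f"duplicate atom index {idx} in ITP")
            by_index[idx] = name
            graph.add_node(name)
            if len(parts) >= 7:
                charges[name] = float(parts[6])
        elif section == "bonds":
            if len(parts) < 2:
                raise ParseError(f"ITP bonds line too short: {raw!r}")
            pending.append((int(parts[0]), int(parts[1])))
    seen = list(by_index.values())
    if len(set(seen)) != len(seen):
        raise ValidationError("duplicate atom names in ITP [atoms] section")
    for i, j in pending:
        if i not in by_index or j not in by_index:
            raise ValidationError(f"ITP bond ({i},{j}) references undeclared atom")
        graph.add_edge(by_index[i], by_index[j])
    return graph, charges


def _read_rtp(text: str, residue: str | None) -> tuple[BondGraph, ChargeTable]:
    """GROMACS .rtp: ``[ RESNAME ]`` headers with [ atoms ] / [ bonds ] blocks."""
    known_sub = {"atoms", "bonds", "bondedtypes", "exclusions", "angles",
                 "dihedrals", "impropers", "cmap"}
    residues: dict[str, dict[str, list[list[str]]]] = {}
    current_res = None
    section = None
    for raw in text.splitlines():
        line = _strip_comment(raw, ";").strip()
        if not line:
            continue
        if line.startswith("["):
            tag = line.strip("[] \t")
            if tag.lower() in known_sub:
                section = tag.lower()
            else:
                current_res = tag
                residues[current_res] = {}
                section = None
            continue
        if current_res is None or section is None:
            continue
        residues[current_res].setdefault(section, []).append(line.split())
    return _build_from_sections(residues, residue, fmt="RTP")


def _read_rtf(text: str, residue: str | None) -> tuple[BondGraph, ChargeTable]:
    """CHARMM .rtf: RESI blocks with ATOM and BOND records."""
    residues: dict[str, dict[str, list[list[str]]]] = {}
    current = None
    for raw in text.splitlines():
        line = _strip_comment(raw, "!").strip()
        if not line:
            continue
        parts = line.split()
        kw = parts[0].upper()
        if kw in ("RESI", "PRES"):
            current = parts[1]
            residues[current] = {}
        elif current is not None and kw == "ATOM" and len(parts) >= 3:
            charge = parts[3] if len(parts) >= 4 else "0.0"
            residues[current].setdefault("atoms", []).append(
                [parts[1], parts[2], charge])
        elif current is not None and kw in ("BOND", "DOUBLE") and len(parts) >= 3:
            names = parts[1:]
            for i in range(0, len(names) - 1, 2):
                residues[current].setdefault("bonds", []).append(
                    [names[i], names[i + 1]])
    # normalise to the RTP column layout (name type charge)
    for res in residues.values():
        res["atoms"] = [[a[0], a[1], a[2]] for a in res.get("atoms", [])]
    return _build_from_sections(residues, residue, fmt="RTF")


def _build_from_sections(residues, residue, fmt) -> tuple[BondGraph, ChargeTable]:
    if residue is None:
        if len(residues) != 1:
            raise NotFoundError(
                f"{fmt} file defines {len(residues)} residues; specify one of "
                f"{sorted(residues)}")
        residue = next(iter(residues))
    if residue not in residues:
        raise NotFoundError(f"residue {residue!r} not found in {fmt} file")
    sections = residues[residue]
    graph = BondGraph()
    charges: ChargeTable = {}
    for parts in sections.get("atoms", []):
        name = parts[0]
        graph.add_node(name)
        if len(parts) >= 3:
            try:
                charges[name] = float(parts[2])
            except ValueError:
                pass
    for parts in sections.get("bonds", []):
        a, b = parts[0], parts[1]
        # skip inter-residue bonds (+/- prefixed names) in rtp files
        if a[0] in "+-" or b[0] in "+-":
            continue
        graph.add_edge(a, b)
    return graph, charges


def read_mol2(text: str) -> tuple[Structure, BondGraph, ChargeTable]:
    """Parse a Tripos MOL2 file into coordinates, bonds and charges."""
    section = None
    atoms: list[Atom] = []
    by_id: dict[int, str] = {}
    graph = BondGraph()
    charges: ChargeTable = {}
    pending: list[tuple[int, int, str]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[9:].upper()
            continue
        if not line or line.startswith("#") or section is None:
            continue
        parts = line.split()
        if section == "ATOM":
            if len(parts) < 6:
                raise ParseError(f"MOL2 atom line too short: {raw!r}")
            aid = int(parts[0])
            name = parts[1]
            xyz = (float(parts[2]), float(parts[3]), float(parts[4]))
            sybyl = parts[5]
            res_seq = int(parts[6]) if len(parts) >= 7 else 1
            res_name = parts[7] if len(parts) >= 8 else "LIG"
            element = sybyl.split(".")[0]
            if len(parts) >= 9:
                charges[name] = float(parts[8])
            by_id[aid] = name
            graph.add_node(name)
            atoms.append(Atom(
                serial=aid, name=name,
                element=element if element.isalpha() else infer_element(name),
                res_name=res_name, res_seq=res_seq, chain_id="", xyz=xyz,
                record_kind="HETATM"))
        elif section == "BOND":
            if len(parts) < 4:
                raise ParseError(f"MOL2 bond line too short: {raw!r}")
            pending.append((int(parts[1]), int(parts[2]), parts[3].lower()))
    for i, j, btype in pending:
        if i not in by_id or j not in by_id:
            raise ValidationError(f"MOL2 bond ({i},{j}) references undeclared atom")
        order, aromatic = _MOL2_ORDERS.get(btype, ("single", False))
        graph.add_edge(by_id[i], by_id[j], order=order, aromatic=aromatic)
    return Structure(atoms=atoms, source_format="MOL2"), graph, charges


def read_crd(text: str) -> Structure:
    """Parse a CHARMM CRD card file (coordinates only; charges ignored)."""
    atoms: list[Atom] = []
    n_expected = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line or line.startswith("*"):
            continue
        parts = line.split()
        if n_expected is None:
            try:
                n_expected = int(parts[0])
            except ValueError:
                raise ParseError(f"CRD line {lineno}: atom count expected") from None
            continue
        if len(parts) < 7:
            raise ParseError(f"CRD line {lineno}: truncated atom record")
        try:
            serial = int(parts[0])
            res_seq = int(parts[1])
            res_name = parts[2]
            name = parts[3]
            xyz = (float(parts[4]), float(parts[5]), float(parts[6]))
        except ValueError as e:
            raise ParseError(f"CRD line {lineno}: {e}") from None
        seg = parts[7] if len(parts) >= 8 else ""
        atoms.append(Atom(
            serial=serial, name=name, element=infer_element(name),
            res_name=res_name, res_seq=res_seq,
            chain_id=seg[:1] if seg else "", xyz=xyz, record_kind="HETATM"))
    return Structure(atoms=atoms, source_format="CRD")


_COORD_EXT = {"pdb", "gro", "crd", "cif"}
_TOPO_EXT = {"itp", "rtf", "rtp"}


def pair_files(args: list[str]) -> list[tuple[str, str]]:
    """Pair coordinate and bonding files for covalent-ligand input.

    Files must alternate coordinates-then-topology (``a.pdb a.itp ...``);
    a lone MOL2 carries both roles and pairs with itself.
    """
    pairs: list[tuple[str, str]] = []
    i = 0
    while i < len(args):
        ext = args[i].rsplit(".", 1)[-1].lower()
        if ext == "mol2":
            pairs.append((args[i], args[i]))
            i += 1
        elif ext in _COORD_EXT:
            if i + 1 >= len(args):
                raise UsageError(
                    f"coordinate file {args[i]!r} has no following bonding file")
            next_ext = args[i + 1].rsplit(".", 1)[-1].lower()
            if next_ext not in _TOPO_EXT:
                raise UsageError(
                    f"expected a bonding file after {args[i]!r}, got {args[i+1]!r}")
            pairs.append((args[i], args[i + 1]))
            i += 2
        elif ext in _TOPO_EXT:
            raise UsageError(
                f"bonding file {args[i]!r} must follow its coordinate file")
        else:
            raise UsageError(f"unrecognised covalent input file {args[i]!r}")
    return pairs
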