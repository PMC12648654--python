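"""Read and write molecular structures in PDB, GRO and mmCIF.

All coordinates are stored internally in angstroms (GRO files, which use
nanometres, are converted on read and write).  Atom order is preserved
exactly as read; only the first model of a multi-model file is kept.
Alternate-location conformers other than blank or ``A`` are dropped with a
logged warning, since co-folding outputs carry single conformers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator

import gemmi

from .errors import ParseError, RangeError, UnsupportedFormatError

logger = logging.getLogger(__name__)

#: Two-letter symbols that begin with H and therefore must not be read as
#: hydrogen when inferring elements from atom names.
_H_METALS = {"HE", "HF", "HG", "HO"}

#: Standard amino acids (plus common cap residues) — never treated as ligands.
PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "ACE", "NME", "NMA",
}


def infer_element(name: str) -> str:
    """Derive an element symbol from an atom name.

    Leading digits are skipped.  A name is hydrogen iff its first alphabetic
    character is ``H`` and its two-letter alphabetic prefix is not a metal
    (He, Hf, Hg, Ho): PDB hydrogen names like ``1HB`` must resolve to H while
    mercury (``HG``) must not.
    """
    alpha = "".join(c for c in name if c.isalpha())
    if not alpha:
        return ""
    prefix2 = alpha[:2].upper()
    if prefix2 in _H_METALS:
        return prefix2.capitalize()
    return alpha[0].upper()


@dataclass(frozen=True)
class Atom:
    """One atomic record: identity, residue membership and position (Å)."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    xyz: tuple[float, float, float]
    alt_loc: str = ""
    record_kind: str = "ATOM"

    def __post_init__(self):
        for c in self.xyz:
            if c != c or c in (float("inf"), float("-inf")):
                raise ValueError(f"non-finite coordinate in atom {self.name!r}")

    @property
    def is_hydrogen(self) -> bool:
        el = self.element or infer_element(self.name)
        return el.upper() == "H"


@dataclass
class Structure:
    """An ordered list of atoms plus provenance."""

    atoms: list[Atom] = field(default_factory=list)
    source_format: str = "PDB"
    title: str | None = None

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class ChainPolicy:
    """Chain ordering policy: alphabetical with the empty chain last."""

    ligand_separate_chain: bool = False


def iter_residues(s: Structure) -> Iterator[tuple[tuple[str, int, str], list[Atom]]]:
    """Yield ``((chain_id, res_seq, res_name), atoms)`` for consecutive residues."""
    key = None
    group: list[Atom] = []
    for a in s.atoms:
        k = (a.chain_id, a.res_seq, a.res_name)
        if k != key and group:
            yield key, group
            group = []
        key = k
        group.append(a)
    if group:
        yield key, group


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_structure(source: str, fmt: str) -> Structure:
    """Parse ``source`` (file content) in the given format (PDB, GRO or CIF)."""
    fmt = fmt.upper().lstrip(".")
    if fmt == "PDB":
        return _read_pdb(source)
    if fmt == "GRO":
        return _read_gro(source)
    if fmt in ("CIF", "MMCIF"):
        return _read_mmcif(source)
    raise UnsupportedFormatError(f"unsupported structure format: {fmt!r}")


def format_of(path: str) -> str:
    """Map a file name to a structure format tag by extension."""
    ext = path.rsplit(".", 1)[-1].upper() if "." in path else ""
    if ext in ("PDB", "GRO"):
        return ext
    if ext in ("CIF", "MMCIF"):
        return "CIF"
    raise UnsupportedFormatError(f"cannot determine structure format of {path!r}")


def _keep_altloc(alt: str, label: str) -> bool:
    if alt in ("", " ", ".", "?", "A"):
        return True
    logger.warning("dropping alternate conformer %r of %s", alt, label)
    return False


def _read_pdb(text: str) -> Structure:
    atoms: list[Atom] = []
    title = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "TITLE" and title is None:
            title = line[10:].strip() or None
        elif rec == "ENDMDL":
            break  # first model only
        elif rec in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise ParseError(f"PDB line {lineno}: truncated atom record")
            try:
                serial = int(line[6:11])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as e:
                raise ParseError(f"PDB line {lineno}: {e}") from None
            name = line[12:16].strip()
            alt = line[16:17].strip()
            if not _keep_altloc(alt, f"PDB line {lineno}"):
                continue
            # residue field spans cols 18-21: CHARMM lipid names are 4 chars
            res_name = line[17:21].strip()
            chain = line[21:22].strip()
            try:
                res_seq = int(line[22:26])
            except ValueError:
                raise ParseError(f"PDB line {lineno}: bad residue number") from None
            element = line[76:78].strip() if len(line) >= 78 else ""
            atoms.append(Atom(
                serial=serial, name=name,
                element=element or infer_element(name),
                res_name=res_name, res_seq=res_seq, chain_id=chain,
                xyz=(x, y, z), alt_loc="" if alt == "A" else alt,
                record_kind=rec,
            ))
    return Structure(atoms=atoms, source_format="PDB", title=title)


def _read_gro(text: str) -> Structure:
    lines = text.splitlines()
    if len(lines) < 2:
        raise ParseError("GRO file: missing header lines")
    title = lines[0].strip() or None
    try:
        n = int(lines[1].strip())
    except ValueError:
        raise ParseError("GRO file line 2: atom count expected") from None
    if len(lines) < 2 + n:
        raise ParseError(f"GRO file: expected {n} atom lines")
    atoms: list[Atom] = []
    for i in range(n):
        line = lines[2 + i]
        lineno = 3 + i
        try:
            res_seq = int(line[0:5])
            res_name = line[5:10].strip()
            name = line[10:15].strip()
            serial = int(line[15:20])
            # nm -> Å
            x = float(line[20:28]) * 10.0
            y = float(line[28:36]) * 10.0
            z = float(line[36:44]) * 10.0
        except ValueError as e:
            raise ParseError(f"GRO line {lineno}: {e}") from None
        atoms.append(Atom(
            serial=serial, name=name, element=infer_element(name),
            res_name=res_name, res_seq=res_seq, chain_id="",
            xyz=(x, y, z),
        ))
    return Structure(atoms=atoms, source_format="GRO", title=title)


def _cif_get(row_get, loop_tags, label: str, auth: str) -> str | None:
    """Fetch a loop value, preferring the label_* tag over auth_*."""
    for tag in (label, auth):
        if tag in loop_tags:
            v = row_get(tag)
            if v not in (None, ".", "?"):
                return v
    return None


def _read_mmcif(text: str) -> Structure:
    try:
        doc = gemmi.cif.read_string(text)
    except (RuntimeError, ValueError) as e:
        raise ParseError(f"mmCIF parse failure: {e}") from None
    block = doc.sole_block()
    prefix = "_atom_site."
    table = block.find_mmcif_category(prefix)
    if not table:
        return Structure(atoms=[], source_format="CIF", title=block.name or None)
    tag_list = [t[len(prefix):] for t in table.tags]
    tags = set(tag_list)
    tag_pos = {t: i for i, t in enumerate(tag_list)}

    def get(row, tag):
        return gemmi.cif.as_string(row[tag_pos[tag]])

    atoms: list[Atom] = []
    first_model = None
    for row in table:
        if "pdbx_PDB_model_num" in tags:
            model = get(row, "pdbx_PDB_model_num")
            if first_model is None:
                first_model = model
            elif model != first_model:
                break
        fetch = lambda lab, auth: _cif_get(lambda t: get(row, t), tags, lab, auth)
        name = fetch("label_atom_id", "auth_atom_id") or ""
        res_name = fetch("label_comp_id", "auth_comp_id") or ""
        chain = fetch("label_asym_id", "auth_asym_id") or ""
        seq = fetch("label_seq_id", "auth_seq_id") or "0"
        alt = fetch("label_alt_id", "auth_alt_id") or ""
        if not _keep_altloc(alt, f"atom {name}"):
            continue
        element = fetch("type_symbol", "type_symbol") or infer_element(name)
        kind = get(row, "group_PDB") if "group_PDB" in tags else "ATOM"
        serial = int(get(row, "id")) if "id" in tags else len(atoms) + 1
        try:
            xyz = tuple(float(get(row, t)) for t in ("Cartn_x", "Cartn_y", "Cartn_z"))
            res_seq = int(seq)
        except (ValueError, IndexError) as e:
            raise ParseError(f"mmCIF atom_site row: {e}") from None
        atoms.append(Atom(
            serial=serial, name=name, element=element, res_name=res_name,
            res_seq=res_seq, chain_id=chain, xyz=xyz,
            alt_loc="" if alt == "A" else alt, record_kind=kind,
        ))
    return Structure(atoms=atoms, source_format="CIF", title=block.name or None)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_structure(s: Structure, fmt: str) -> str:
    """Serialise a structure as PDB or GRO text (canonical form).

    Serials are renumbered from 1, so a write→read→write cycle is a fixed
    point on the emitted text.
    """
    fmt = fmt.upper().lstrip(".")
    if fmt == "PDB":
        return _write_pdb(s)
    if fmt == "GRO":
        return _write_gro(s)
    raise UnsupportedFormatError(f"unsupported output format: {fmt!r}")


def _pdb_name_field(name: str, element: str) -> str:
    # Names of ≤3 chars whose element is 1-2 chars start in column 14.
    if len(name) >= 4:
        return f"{name:<4.4s}"
    return f" {name:<3s}"


def _check_range(v: float, lo: float, hi: float, what: str) -> None:
    if not (lo <= v <= hi):
        raise RangeError(f"{what} {v} outside representable range [{lo}, {hi}]")


def _write_pdb(s: Structure) -> str:
    out = []
    if s.title:
        out.append(f"TITLE     {s.title}")
    prev_chain = None
    serial = 0
    for a in s.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            out.append("TER")
        prev_chain = a.chain_id
        serial += 1
        for c in a.xyz:
            _check_range(c, -999.999, 9999.999, "coordinate")
        _check_range(a.res_seq, -999, 9999, "residue number")
        out.append(
            f"{a.record_kind:<6.6s}{serial % 100000:>5d} "
            f"{_pdb_name_field(a.name, a.element)}{a.alt_loc or ' ':1.1s}"
            f"{a.res_name:<4.4s}{a.chain_id or ' ':1.1s}{a.res_seq:>4d}    "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}"
        )
    if s.atoms:
        out.append("TER")
    out.append("END")
    return "\n".join(out) + "\n"


def _write_gro(s: Structure) -> str:
    out = [s.title or "ccd2md structure", f"{len(s.atoms):>5d}"]
    for i, a in enumerate(s.atoms, start=1):
        nm = tuple(c / 10.0 for c in a.xyz)
        for c in nm:
            _check_range(c, -999.999, 9999.999, "coordinate (nm)")
        out.append(
            f"{a.res_seq % 100000:>5d}{a.res_name:<5.5s}{a.name:>5.5s}"
            f"{i % 100000:>5d}{nm[0]:8.3f}{nm[1]:8.3f}{nm[2]:8.3f}"
        )
    out.append(f"{0.0:10.5f}{0.0:10.5f}{0.0:10.5f}")
    return "\n".join(out) + "\n"


def write_mmcif(s: Structure, block_name: str = "structure") -> str:
    """Emit a minimal atom_site loop (used by the fixtures cross-format suite)."""
    out = [
        f"data_{block_name}",
        "loop_",
        "_atom_site.group_PDB",
        "_atom_site.id",
        "_atom_site.type_symbol",
        "_atom_site.label_atom_id",
        "_atom_site.label_alt_id",
        "_atom_site.label_comp_id",
        "_atom_site.label_asym_id",
        "_atom_site.label_seq_id",
        "_atom_site.Cartn_x",
        "_atom_site.Cartn_y",
        "_atom_site.Cartn_z",
    ]
    for i, a in enumerate(s.atoms, start=1):
        out.append(
            f"{a.record_kind} {i} {a.element or '?'} {a.name} "
            f"{a.alt_loc or '.'} {a.res_name} {a.chain_id or '.'} {a.res_seq} "
            f"{a.xyz[0]:.3f} {a.xyz[1]:.3f} {a.xyz[2]:.3f}"
        )
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def strip_hydrogens(s: Structure) -> Structure:
    """Remove all hydrogen atoms, preserving the order of the rest."""
    kept = [a for a in s.atoms if not a.is_hydrogen]
    return replace(s, atoms=kept)


def _chain_sort_key(chain_id: str) -> tuple[int, str]:
    # empty/blank chain sorts after everything else; otherwise ASCII order
    return (1, "") if chain_id == "" else (0, chain_id)


def reorder_chains(s: Structure, policy: ChainPolicy | None = None) -> Structure:
    """Sort chains alphabetically (ASCII), empty chain last; stable within chains."""
    order: list[str] = []
    for a in s.atoms:
        if a.chain_id not in order:
            order.append(a.chain_id)
    wanted = sorted(order, key=_chain_sort_key)
    if wanted == order:
        return s
    buckets: dict[str, list[Atom]] = {c: [] for c in order}
    for a in s.atoms:
        buckets[a.chain_id].append(a)
    atoms = [a for c in wanted for a in buckets[c]]
    return replace(s, atoms=atoms)
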