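"""The ligand master table and per-ligand atom / bead mapping files.

The master table (``database.csv``) links each force-field residue name to
its CCD code and coarse-grained name, with a category tag (lipid, ptm or
detergent).  Per-ligand atom maps give the correspondence between source
(CCD) and target (force-field) atom names; bead maps assign heavy atoms to
coarse-grained beads.

Mapping-file dialect
--------------------
Atom maps (``<FF>.txt``) are whitespace-separated two-column files,
``source target`` per line, ``#`` comments, line order significant: the
line order defines the force-field output atom order.  An optional
``# ccd-order: n1 n2 ...`` directive records the canonical CCD-side atom
order used when converting back towards CCD naming (defaults to line
order).  Bead maps (``<FF>_CG.txt``) hold one bead per line: the bead name
followed by its contributing heavy atoms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import ConflictError, ValidationError

MASTER_COLUMNS = ["ff_name", "ccd_code", "cg_name", "category"]
CATEGORIES = {"lipid", "ptm", "detergent"}


@dataclass(frozen=True)
class LigandEntry:
    ff_name: str
    ccd_code: str | None = None
    cg_name: str | None = None
    category: str = "lipid"
    user_defined: bool = False


@dataclass(frozen=True)
class AtomMap:
    """Per-ligand bijection between source (CCD) and target (FF) atom names.

    ``entries`` are ``(source, target)`` pairs listed in target output
    order.  ``source_order`` lists the source names in canonical CCD output
    order, used by the reverse conversion; it defaults to entry order.
    """

    ligand: str
    entries: tuple[tuple[str, str], ...]
    source_scheme: str = "ccd"
    source_order: tuple[str, ...] = ()

    def __post_init__(self):
        src = [s for s, _ in self.entries]
        tgt = [t for _, t in self.entries]
        if len(set(src)) != len(src) or len(set(tgt)) != len(tgt):
            raise ValidationError(f"atom map for {self.ligand!r} is not a bijection")
        if not self.source_order:
            object.__setattr__(self, "source_order", tuple(src))
        elif set(self.source_order) != set(src):
            raise ValidationError(
                f"atom map for {self.ligand!r}: ccd-order names do not match "
                f"source names")

    @property
    def source_names(self) -> set[str]:
        return {s for s, _ in self.entries}

    @property
    def target_names(self) -> set[str]:
        return {t for _, t in self.entries}

    def to_target(self) -> dict[str, str]:
        return {s: t for s, t in self.entries}

    def to_source(self) -> dict[str, str]:
        return {t: s for s, t in self.entries}

    def inverted(self) -> "AtomMap":
        """Swap source and target roles; output order becomes the CCD order."""
        to_t = self.to_target()
        entries = tuple((to_t[s], s) for s in self.source_order)
        return AtomMap(ligand=self.ligand, entries=entries,
                       source_scheme="ff",
                       source_order=tuple(t for _, t in self.entries))


@dataclass(frozen=True)
class BeadMap:
    """Ordered coarse-grained beads, each naming its contributing heavy atoms."""

    ligand: str
    beads: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self):
        for name, members in self.beads:
            if len(members) < 1:
                raise ValidationError(
                    f"bead {name!r} of {self.ligand!r} has no contributing atoms")

    def atom_usage(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, members in self.beads:
            for m in members:
                counts[m] = counts.get(m, 0) + 1
        return counts


@dataclass
class MappingDatabase:
    entries: dict[str, LigandEntry] = field(default_factory=dict)
    atom_maps: dict[str, AtomMap] = field(default_factory=dict)
    bead_maps: dict[str, BeadMap] = field(default_factory=dict)
    _shadowed: dict[str, LigandEntry] = field(default_factory=dict)

    def copy(self) -> "MappingDatabase":
        return MappingDatabase(dict(self.entries), dict(self.atom_maps),
                               dict(self.bead_maps), dict(self._shadowed))

    def __eq__(self, other):
        if not isinstance(other, MappingDatabase):
            return NotImplemented
        return (self.entries == other.entries
                and self.atom_maps == other.atom_maps
                and self.bead_maps == other.bead_maps)


def parse_atom_map(ligand: str, text: str) -> AtomMap:
    entries: list[tuple[str, str]] = []
    source_order: tuple[str, ...] = ()
    for raw in text.splitlines():
        stripped = raw.strip()
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.lower().startswith("ccd-order:"):
                source_order = tuple(body.split(":", 1)[1].split())
            continue
        if not stripped:
            continue
        parts = stripped.split()
        if len(parts) != 2:
            raise ValidationError(
                f"atom map for {ligand!r}: expected two columns, got {raw!r}")
        entries.append((parts[0], parts[1]))
    return AtomMap(ligand=ligand, entries=tuple(entries),
                   source_order=source_order)


def format_atom_map(m: AtomMap) -> str:
    lines = [f"# atom map for {m.ligand}: source target"]
    if tuple(m.source_order) != tuple(s for s, _ in m.entries):
        lines.append("# ccd-order: " + " ".join(m.source_order))
    lines += [f"{s} {t}" for s, t in m.entries]
    return "\n".join(lines) + "\n"


def parse_bead_map(ligand: str, text: str) -> BeadMap:
    beads: list[tuple[str, tuple[str, ...]]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValidationError(
                f"bead map for {ligand!r}: bead line needs atoms: {raw!r}")
        beads.append((parts[0], tuple(parts[1:])))
    return BeadMap(ligand=ligand, beads=tuple(beads))


def format_bead_map(m: BeadMap) -> str:
    lines = [f"# bead map for {m.ligand}: bead atoms..."]
    lines += [f"{name} " + " ".join(members) for name, members in m.beads]
    return "\n".join(lines) + "\n"


def load_database(master_table: str, map_files: dict[str, str] | None = None
                  ) -> MappingDatabase:
    """Build and cross-validate a database from CSV text and mapping files.

    ``map_files`` maps file names (``<FF>.txt``, ``<FF>_CG.txt``) to their
    contents.
    """
    map_files = map_files or {}
    df = pd.read_csv(io.StringIO(master_table), dtype=str,
                     skipinitialspace=True).fillna("")
    missing = [c for c in MASTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"master table missing columns {missing}")
    db = MappingDatabase()
    for _, row in df.iterrows():
        ff = row["ff_name"].strip()
        if not ff:
            raise ValidationError("master table row with empty ff_name")
        if ff in db.entries:
            raise ValidationError(f"duplicate ff_name {ff!r} in master table")
        ccd = row["ccd_code"].strip() or None
        if ccd and lookup_by_ccd(db, ccd) is not None:
            raise ValidationError(f"duplicate ccd_code {ccd!r} in master table")
        cat = row["category"].strip() or "lipid"
        if cat not in CATEGORIES:
            raise ValidationError(f"ligand {ff!r}: unknown category {cat!r}")
        db.entries[ff] = LigandEntry(
            ff_name=ff, ccd_code=ccd,
            cg_name=row["cg_name"].strip() or None, category=cat)
    for fname, text in sorted(map_files.items()):
        stem = fname.rsplit("/", 1)[-1]
        if stem.endswith("_CG.txt"):
            ff = stem[:-len("_CG.txt")]
            _require_entry(db, ff, fname)
            db.bead_maps[ff] = parse_bead_map(ff, text)
        elif stem.endswith(".txt"):
            ff = stem[:-len(".txt")]
            _require_entry(db, ff, fname)
            db.atom_maps[ff] = parse_atom_map(ff, text)
        else:
            raise ValidationError(f"unrecognised mapping file {fname!r}")
    validate_database(db)
    return db


def _require_entry(db: MappingDatabase, ff: str, fname: str) -> None:
    if ff not in db.entries:
        raise ValidationError(
            f"mapping file {fname!r} has no master-table entry {ff!r}")


def validate_database(db: MappingDatabase) -> list[str]:
    """Cross-validate maps; raise on hard violations, return soft reports."""
    reports: list[str] = []
    for ff, bm in db.bead_maps.items():
        am = db.atom_maps.get(ff)
        if am is not None:
            unknown = {m for _, members in bm.beads for m in members
                       if m not in am.target_names}
            if unknown:
                raise ValidationError(
                    f"bead map for {ff!r} references unknown atoms "
                    f"{sorted(unknown)}")
            usage = bm.atom_usage()
            unused = sorted(am.target_names - set(usage))
            shared = sorted(a for a, n in usage.items() if n > 1)
            if unused:
                reports.append(f"{ff}: atoms in no bead: {unused}")
            if shared:
                reports.append(f"{ff}: atoms in multiple beads: {shared}")
    return reports


def lookup_by_ccd(db: MappingDatabase, code: str) -> LigandEntry | None:
    """Find the entry with the given CCD (or user-CCD) code, or None.

    User-defined components supersede CCD entries with the same code.
    """
    hit = None
    for e in db.entries.values():
        if e.ccd_code == code:
            if e.user_defined:
                return e
            hit = e
    return hit


def lookup_by_ff(db: MappingDatabase, name: str) -> LigandEntry | None:
    return db.entries.get(name)


def register_user_component(db: MappingDatabase, component, atom_map: AtomMap,
                            cg_name: str | None = None,
                            category: str = "lipid") -> MappingDatabase:
    """Add a user-defined component; it shadows any same-coded CCD entry.

    The component's id becomes the new entry's CCD code; the atom map's
    ligand name is the force-field residue name.  A clash with an existing
    force-field name that is not this component is an error.
    """
    code = component.comp_id
    ff = atom_map.ligand
    new = db.copy()
    if ff in new.entries and new.entries[ff].ccd_code != code:
        raise ConflictError(
            f"user component {code!r} maps to force-field name {ff!r}, which "
            f"already belongs to a different ligand")
    existing = lookup_by_ccd(new, code)
    if existing is not None:
        if existing.ff_name != ff:
            # shadow the CCD entry: the user definition supersedes it
            new._shadowed[code] = existing
            new.entries[existing.ff_name] = replace(existing, ccd_code=None)
    new.entries[ff] = LigandEntry(ff_name=ff, ccd_code=code, cg_name=cg_name,
                                  category=category, user_defined=True)
    new.atom_maps[ff] = atom_map
    return new


def deregister_user_component(db: MappingDatabase, code: str) -> MappingDatabase:
    """Remove a user component, restoring any entry it shadowed."""
    new = db.copy()
    target = None
    for ff, e in new.entries.items():
        if e.user_defined and e.ccd_code == code:
            target = ff
    if target is None:
        return new
    del new.entries[target]
    new.atom_maps.pop(target, None)
    new.bead_maps.pop(target, None)
    shadowed = new._shadowed.pop(code, None)
    if shadowed is not None:
        new.entries[shadowed.ff_name] = shadowed
    return new
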