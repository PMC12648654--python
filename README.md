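# ccd2md

Co-folding programs (AlphaFold3, Chai-1, Boltz-1, Protenix, RosettaFold
All-Atom) predict holo protein structures with bound ligands, but their
outputs name and order ligand atoms by PDB Chemical Component Dictionary
(CCD) codes or SMILES order — not by the conventions a molecular dynamics
force field expects. `ccd2md` closes that gap for people preparing
protein–lipid (and general protein–ligand) systems for GROMACS: it renames
and reorders ligand atoms and residues between CCD and CHARMM-style
force-field naming, maps ligands onto Martini-style coarse-grained beads,
and builds user-defined CCD components plus complete AlphaFold3 job
documents from arbitrary ligand coordinates.

## What it does

- **Atomistic conversion** (`ccd2at` / `at2ccd`): per-ligand atom maps — a
  bijection σ between CCD and force-field atom names with a defined output
  order — are applied residue by residue. Coordinates are untouched;
  hydrogens (absent from co-folding outputs) are stripped; chains are
  processed alphabetically with empty chains last; ligands either continue
  the protein's residue numbering or move to a fresh chain (`-L`).
  Ligands not in the database pass through unchanged.
- **User-CCD generation** (`pos2cif`): from coordinates (PDB/GRO/CRD/MOL2),
  bonds are taken from topology files (ITP/RTF/RTP/MOL2) when given, else
  inferred by the hard-cutoff rule *bond(i,j) ⇔ ‖xᵢ−xⱼ‖ ≤ r_c* with
  r_c = 1.4 Å. Partial charges q round to formal charges by
  *n = nearest-integer(q); charge = n if |q| ≥ c·max(|n|,1) else 0* with
  c = 0.75 e. Covalent multi-part ligands are merged with first-instance
  ideal coordinates. Output is chem_comp CIF per component plus an
  AlphaFold3 job JSON (dialect `alphafold3`, version 2, seeds `[1]`,
  title `pos2cif_system` by default).
- **Coarse-grained conversion** (`ccd2cg` / `at2cg`): each Martini bead b
  with contributing heavy atoms A_b is placed at the centre of mass
  *x_b = Σ_{i∈A_b} mᵢxᵢ / Σ mᵢ* using standard atomic weights; ligand
  beads carry no chain and continue the protein's residue numbering.
  Protein coarse-graining, elastic/Go̅ networks and membrane embedding are
  delegated to external tools (Martinize2, MemPrO, CG2AT) behind planned,
  logged adapter invocations.

A fixtures module generates toy ligands, matched multi-format structure
files, mapping files and topology files with known ground truth, so the
whole suite is testable offline; a small internally consistent mapping
database (master `database.csv` plus per-ligand atom/bead maps) ships with
the package.

## Worked example

```python
from ccd2md import fixtures, convert_ligands, CCD_TO_FF, FF_TO_CCD

db = fixtures.build_default_database()
lig = fixtures.default_ligands()["CHL1"]          # toy cholesterol, CCD code CLR
out, report = convert_ligands(lig.ccd_structure, db, CCD_TO_FF)
print(report.converted)
print([a.name for a in out.atoms][:4])
back, _ = convert_ligands(out, db, FF_TO_CCD)
print([a.xyz for a in back.atoms] == [a.xyz for a in lig.ccd_structure.atoms])
```

prints

```
[('CLR', 'CHL1', '', 1)]
['C1', 'C2', 'O3', 'N4']
True
```

— the CLR-coded residue was renamed to CHL1 with atoms emitted in the
force-field map order, and the reverse conversion restored the original
atom order with coordinates bitwise unchanged.

From the shell, the same conversion is

```sh
ccd2at input.pdb output.pdb        # CCD -> CHARMM naming
at2ccd output.pdb back.pdb         # and back
pos2cif -n POPS -f POPS.pdb -p MSEQVKLV -p 2   # user CCD + AF3 job (output.json)
ccd2cg input.pdb cg.pdb            # CCD -> Martini beads
```

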