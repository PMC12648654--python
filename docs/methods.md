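# Methods

## Problem and model

Co-folding outputs name ligand atoms by CCD code (or SMILES order), while
simulation force fields expect their own residue names, atom names and atom
order. The conversion model is purely combinatorial: for each supported
ligand a stored atom map σ gives a bijection between source and target
heavy-atom names together with the target-side output order, and the
converter applies σ residue-wise without touching coordinates. There is no
chemistry in the conversion itself — maps are data, not derived — so the
correctness questions are exactness questions: bijectivity, order
preservation, conservation of atoms and coordinates, and invertibility.

Two small numerical models sit around that core:

- **Bond perception.** When no bonding file is supplied, the user-CCD
  generator bonds atom pairs at Euclidean separation ≤ r_c. The cutoff is
  closed at the boundary (a pair at exactly r_c is bonded); r_c defaults to
  1.4 Å, chosen to capture covalent heavy-atom distances (C–C ≈ 1.5 Å is
  *not* captured at the default — callers with stretched geometries pass a
  larger `-b`; the default targets idealised/minimised inputs). All emitted
  bonds are single and nonaromatic: AlphaFold3 requires order and
  aromaticity fields but does not use them for inference.
- **Formal charges.** Partial charges q from topology files are reduced to
  integers with a cutoff c (default 0.75 e): with n the integer nearest to
  q (half rounds away from zero), the formal charge is n when
  |q| ≥ c·max(|n|, 1) and 0 otherwise. The published interface fixes only
  the cutoff, not the formula; this rule is monotone in |q|, reduces to
  the intuitive threshold for |q| ≤ 1, and scales the requirement with the
  magnitude of the target integer so that a ±2 charge needs proportionally
  stronger evidence.
- **Bead placement.** A coarse-grained bead is the centre of mass of its
  contributing heavy atoms under standard atomic weights (element weights,
  not force-field masses — the force-field mass tables are licensed data
  and the difference is far below bead resolution). Hydrogens, when
  present at all, are excluded from the sum rather than rejected, matching
  the expectation that co-folding outputs omit them.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| bond cutoff r_c | 1.4 | Å | proximity bond perception (closed bound) |
| charge cutoff c | 0.75 | e | formal-charge rounding threshold |
| job JSON name | `output.json` | — | AlphaFold3 job document |
| dialect / version | `alphafold3` / 2 | — | job document header |
| title | `pos2cif_system` | — | job name |
| model seeds | `[1]` | — | job seeds |

All are overridable on the `pos2cif` command line; the defaults are the
zero-configuration state.

## Design choices where the design was open

- **Reverse-direction atom order.** An atom map's entry order defines the
  force-field output order. The inverse conversion needs a CCD-side order
  too; map files record it in an optional `# ccd-order:` directive
  (defaulting to entry order). This makes ccd→ff→ccd an exact identity on
  names, order and coordinates, which the test suite asserts bitwise.
- **Chain handling.** "Alphabetical" chain order is ASCII codepoint order
  with the blank chain last — a total order consistent with the printed
  policy. The separate-ligand-chain option allocates the first unused
  uppercase letter and numbers ligand residues from 1; without it, ligand
  residues keep their chain and renumber to continue the preceding
  protein's numbering. The reverse converter mirrors the same policy (the
  symmetry is an assumption; the original interface is silent).
- **Element inference.** When a PDB element column is blank, leading
  digits are skipped and an atom is hydrogen iff its first alphabetic
  character is H and its two-letter prefix is not He/Hf/Hg/Ho — so `1HB`
  strips as hydrogen while mercury survives.
- **Alternate conformers.** Only blank or `A` alt-locs are kept (dropped
  conformers are logged). Co-folding outputs are single-conformer; the
  rule exists to make hand-made inputs deterministic. Multi-model files
  contribute their first model only.
- **Covalent merging.** Repeated components take the first instance's
  coordinates as ideal coordinates; second and later instances get numeric
  atom-name suffixes (`C1` → `C1_2`), advancing to the next free numeral
  if a different part already claimed the name. Inter-part bonds use
  supplied topologies where given; the proximity fallback applies across
  part boundaries only, judged on each part's *actual* coordinates (the
  real covalent geometry), while emitted ideal coordinates may come from
  an earlier instance. Renaming covalent ligands is rejected. Mixed
  hydrogen content across the parts of one component is an error unless
  hydrogens are kept explicitly.
- **Job document grammar.** Protein copies may be given as repeated
  sequences, a sequence followed by a count, or a mixture; a numeral sets
  the count of the sequence before it and identical sequences aggregate.
  A covalent ligand is emitted as a single user-CCD component (one ligand
  entity in the job; the alternative — several entities joined by
  bondedAtomPairs — is intentionally not produced).
- **External tools.** Martinize2, pdb2gmx, MemPrO and CG2AT are
  orchestrated, not reimplemented: argument-list construction is pure and
  unit-tested (elastic network by default, Go̅ incompatible with membrane
  embedding, `-resid input` appended when PTMs are present unless the user
  chose `-resid mol`), and execution is injected so runs without the tools
  plan, log and skip with a notice. Consequently the protein half of a CG
  output produced without Martinize2 is a placeholder copy of the
  atomistic protein; the ligand bead half is exact.

## The synthetic-data generator

Fixture ligands are toy shapes — chains (120° zig-zag), rings and
tetrahedra with a 1.0 Å bond length — built so that the intended bond
graph is exactly what the default 1.4 Å cutoff recovers: bonded neighbours
at 1.0 Å, closest non-bonded pairs ≥ √2 Å. Each fixture bundles a
force-field-named canonical copy, a CCD-named copy in a seeded scrambled
order, the connecting atom map, a bead partition covering every heavy atom
exactly once, a ground-truth bond graph and a charge table, plus emissions
of the same molecule as PDB, GRO, mmCIF, MOL2, ITP and RTP text. The
shipped database mirrors the documented CCD↔CHARMM↔Martini name pairs
(CLR/CHL1, POV/POPC, 6OU/POPE, PGW/POPG, D39/POPS, PCF/DPPC, one PTM, one
detergent) but its atom contents are toy: real CHARMM36/Martini mapping
content is licensed force-field data and is deliberately not reproduced.

What passing tests therefore show: the conversion machinery is exact on
any internally consistent mapping database, formats round-trip at their
printed precision, and the numerical rules match independent oracles
(all-pairs bond search, explicit Σmᵢxᵢ/Σmᵢ sums, the closed-form charge
rule). What they do not show: chemical correctness of any real lipid's
mapping, behaviour on disordered or clashed co-folded geometries, or the
output of the external tools themselves.

## Numerical notes

- Internal unit is Å everywhere; GRO converts (×10 / ÷10) on read and
  write. PDB coordinates carry 0.001 Å precision, GRO 0.001 nm; the
  cross-format equivalence tests use 0.01 Å.
- The writer renumbers serials from 1, so write→read→write is a byte-level
  fixed point; CIF emission is a deterministic formatter, so
  emit→parse→emit is byte-stable.
- The PDB residue-name field spans columns 18–21 on read and write:
  CHARMM lipid names are four characters. Standard three-character names
  are unaffected.
- Oracle comparisons on bead positions and rigid-motion invariance use an
  absolute tolerance of 1e-9 Å; bond-edge sets are compared exactly
  (random clouds essentially never place a pair within floating-point
  distance of the cutoff, and the fixture geometries keep a ≥ 0.01 Å
  margin).
- Problem sizes in the test and acceptance runs — 50 generated ligands for
  round trips, 100 random clouds of up to 200 atoms for bond inference, 50
  lipids for bead oracles, a 25-point cutoff sweep — are the package's
  chosen verification scale; each completes in seconds.

## Known limitations

- No CONECT records, biological-assembly expansion or multi-model support
  beyond the first model.
- CRD files contribute coordinates only; their charge column is ignored in
  favour of topology files.
- RTF/RTP angle, dihedral and improper sections are ignored — only
  connectivity and charges are consumed.
- The shipped mapping content is fixture-scale; users supply their own
  maps for real ligands (the mapping-file dialects are documented in
  `ccd2md.mapping_db`).
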