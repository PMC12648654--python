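import pytest

from ccd2md import fixtures


@pytest.fixture(scope="session")
def db():
    return fixtures.build_default_database()


@pytest.fixture(scope="session")
def ligands():
    return fixtures.default_ligands()


@pytest.fixture(scope="session")
def chl(ligands):
    """The cholesterol-like toy ligand (CLR ↔ CHL1)."""
    return ligands["CHL1"]


def varied_spec(seed: int, charges: bool = False) -> fixtures.ToyLigandSpec:
    """A deterministic ligand spec whose shape and size vary with the seed."""
    geometry = ("chain", "ring", "tetrahedral")[seed % 3]
    n = {"chain": 4 + seed % 7, "ring": 3 + seed % 6,
         "tetrahedral": 2 + seed % 4}[geometry]
    q = tuple(((-1) ** i) * (0.1 * ((seed + i) % 11)) for i in range(n)) \
        if charges else None
    return fixtures.ToyLigandSpec(
        name_ccd=f"Z{seed:02d}", name_ff=f"LG{seed:02d}",
        name_cg=f"LG{seed:02d}", n_heavy=n, geometry=geometry,
        charges=q, seed=seed)
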