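from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import ladkit as lk

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def pdb_atom_line(serial, name, resname, chain, resseq, x, y, z,
                  altloc=" ", icode=" ", occupancy=1.0, element=None,
                  record="ATOM") -> str:
    """One fixed-width PDB ATOM/HETATM record."""
    element = element or name[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:<3s} {chain}"
        f"{resseq:>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {element:>2s}  "
    )


def make_pdb_text(lines: list[str]) -> str:
    return "\n".join(lines + ["END"]) + "\n"


@pytest.fixture
def two_residue_pdb() -> str:
    """Minimal 2-residue chain A with all four backbone atoms each."""
    lines = []
    serial = 1
    for resseq, base_x in ((1, 0.0), (2, 3.8)):
        for name, dx in (("N", -1.4), ("CA", 0.0), ("C", 1.5), ("O", 1.6)):
            lines.append(pdb_atom_line(serial, name, "ALA", "A", resseq,
                                       base_x + dx, 0.1 * serial, 0.0))
            serial += 1
    return make_pdb_text(lines)


@pytest.fixture(scope="session")
def helix10() -> lk.BackboneStructure:
    return lk.make_toy_chain(10, "helix", chain_id="helix10")


@pytest.fixture(scope="session")
def helix10_mesh(helix10) -> lk.TriMesh:
    return lk.build_surface(helix10)


@pytest.fixture(scope="session")
def helix10_assoc(helix10, helix10_mesh) -> lk.VertexAssociation:
    return lk.associate_vertices(helix10_mesh, helix10)


@pytest.fixture(scope="session")
def icosphere4() -> lk.TriMesh:
    return lk.make_analytic_mesh("icosphere", subdivisions=4)


def random_profile(n: int, rng: np.random.Generator, metric: str = "ED",
                   window: int = 9, structure_id: str = "p") -> lk.LADProfile:
    values = rng.uniform(2.0, 12.0, n)
    return lk.LADProfile(
        structure_id=structure_id,
        metric=metric,
        window=window,
        entries=[(i + 1, float(v)) for i, v in enumerate(values)],
    )
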