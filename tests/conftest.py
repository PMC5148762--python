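import numpy as np
import pytest

from adsorbmc import (
    MolecularStructure,
    assign_groups,
    build_alpha_helix,
    build_graphene,
)
from adsorbmc.parameters import Group

LK_SEQUENCE = "LKKLLKLLKKLLKL"


@pytest.fixture(scope="session")
def lk_helix():
    """Parameterized 14-residue amphipathic leucine/lysine helix fixture."""
    return assign_groups(build_alpha_helix(LK_SEQUENCE))


@pytest.fixture(scope="session")
def graphene():
    return build_graphene(10, 10)


def toy_structure(
    positions,
    eps=0.3,
    rmin_half=2.0,
    radius=1.7,
    group=Group.HYDROPHOBIC_SIDECHAIN,
    names=None,
) -> MolecularStructure:
    """Hand-built structure for toy energy/MC systems."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    eps = np.broadcast_to(np.asarray(eps, dtype=float), (n,)).copy()
    rmin_half = np.broadcast_to(np.asarray(rmin_half, dtype=float), (n,)).copy()
    radius = np.broadcast_to(np.asarray(radius, dtype=float), (n,)).copy()
    group_arr = np.broadcast_to(np.asarray(group, dtype=np.int64), (n,)).copy()
    if names is None:
        names = [f"X{i}" for i in range(n)]
    return MolecularStructure(
        serial=np.arange(1, n + 1, dtype=np.int64),
        name=np.asarray(names, dtype="U6"),
        element=np.asarray(["C"] * n, dtype="U2"),
        residue_name=np.asarray(["TOY"] * n, dtype="U4"),
        residue_index=np.arange(1, n + 1, dtype=np.int64),
        positions=positions,
        lj_epsilon=eps,
        lj_rmin_half=rmin_half,
        sasa_radius=radius,
        group=group_arr,
    )


@pytest.fixture()
def ala_pdb(tmp_path):
    """A single-alanine PDB file with 10 atoms (5 heavy + 5 hydrogens)."""
    lines = [
        ("ATOM", 1, "N", "ALA", 1, 0.000, 0.000, 0.000, "N"),
        ("ATOM", 2, "CA", "ALA", 1, 1.458, 0.000, 0.000, "C"),
        ("ATOM", 3, "C", "ALA", 1, 2.009, 1.420, 0.000, "C"),
        ("ATOM", 4, "O", "ALA", 1, 1.251, 2.390, 0.000, "O"),
        ("ATOM", 5, "CB", "ALA", 1, 1.988, -0.773, -1.199, "C"),
        ("ATOM", 6, "H", "ALA", 1, -0.500, -0.800, 0.000, "H"),
        ("ATOM", 7, "HA", "ALA", 1, 1.700, 0.500, 0.900, "H"),
        ("ATOM", 8, "HB1", "ALA", 1, 1.600, -1.780, -1.100, "H"),
        ("ATOM", 9, "HB2", "ALA", 1, 3.070, -0.800, -1.150, "H"),
        ("ATOM", 10, "HB3", "ALA", 1, 1.700, -0.320, -2.140, "H"),
    ]
    path = tmp_path / "ala.pdb"
    with path.open("w") as fh:
        for rec, serial, name, resn, resi, x, y, z, el in lines:
            name_field = f" {name:<3s}" if len(name) < 4 else name
            fh.write(
                f"{rec:<6s}{serial:5d} {name_field} {resn:<4s}A{resi:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {el:>2s}\n"
            )
        fh.write("END\n")
    return path
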