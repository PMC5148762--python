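"""Solvation-group classification and Lennard-Jones parameter tables.

The scoring model partitions every heavy atom of a protein into one of four
solvation groups (hydrophobic/hydrophilic x sidechain/backbone); surface
carbons form a fifth group.  Each group carries a surface-tension weight
(sigma, kJ/(mol*A^2)) that multiplies the atom's solvent-accessible surface
area to give the nonpolar solvation energy.  Lennard-Jones well depths and
minimum-distance radii follow the CHARMM22 convention; a compact
(residue, atom-name) -> type table is packaged here and may be overridden
from a TSV file.
"""

from __future__ import annotations

import enum
from pathlib import Path

from .constants import SASA_RADII

__all__ = [
    "Group",
    "DEFAULT_SIGMA",
    "lookup_lj",
    "classify_atom",
    "sasa_radius_for_element",
    "load_parameter_overrides",
    "UnknownResidueError",
]


class Group(enum.IntEnum):
    """Solvation group labels for the surface-tension (sigma) model."""

    HYDROPHOBIC_SIDECHAIN = 0
    HYDROPHILIC_SIDECHAIN = 1
    HYDROPHOBIC_BACKBONE = 2
    HYDROPHILIC_BACKBONE = 3
    SURFACE_CARBON = 4
    #: nonpolar hydrogens folded into their heavy atom (heavy-atom model)
    EXCLUDED = 5


#: Default surface tensions, kJ/(mol*A^2).
DEFAULT_SIGMA: dict[Group, float] = {
    Group.HYDROPHOBIC_SIDECHAIN: 100.0,
    Group.HYDROPHILIC_SIDECHAIN: -100.0,
    Group.HYDROPHOBIC_BACKBONE: 100.0,
    Group.HYDROPHILIC_BACKBONE: -100.0,
    Group.SURFACE_CARBON: 100.0,
}

#: Residues whose sidechains are hydrophobic in the sigma model.
HYDROPHOBIC_RESIDUES = {"GLY", "ALA", "VAL", "LEU", "ILE", "MET", "PRO", "PHE", "TRP"}
#: Residues whose sidechains are hydrophilic.
HYDROPHILIC_RESIDUES = {"SER", "THR", "ASN", "GLN", "CYS", "ARG", "ASP", "HIS", "LYS", "GLU"}

#: Tyr is split: aromatic ring (and the aliphatic CB linker) hydrophobic,
#: hydroxyl oxygen hydrophilic.  The partition must be total.
TYR_RING_ATOMS = {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}
TYR_HYDROXYL_ATOMS = {"OH"}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

KCAL_TO_KJ = 4.184

# CHARMM22-style LJ types: (epsilon, kcal/mol; Rmin/2, A)
_LJ_TYPES = {
    "C": (0.110, 2.000),     # carbonyl / guanidinium / amide carbon
    "CT1": (0.020, 2.275),   # aliphatic CH
    "CT2": (0.055, 2.175),   # aliphatic CH2
    "CT3": (0.080, 2.060),   # aliphatic CH3
    "CAro": (0.070, 1.9924), # aromatic carbon (also graphene)
    "NH1": (0.200, 1.850),   # amide / amine nitrogen
    "O": (0.120, 1.700),     # carbonyl / carboxylate oxygen
    "OH1": (0.1521, 1.770),  # hydroxyl oxygen
    "S": (0.450, 2.000),     # thioether / thiol sulfur
    "H": (0.046, 0.2245),
}

# (residue, atom) -> LJ type, for sidechain atoms that are not covered by the
# per-element fallback.  Backbone atoms are handled uniformly.
_SIDECHAIN_TYPE: dict[tuple[str, str], str] = {}


def _register(residue: str, mapping: dict[str, str]) -> None:
    for atom, lj_type in mapping.items():
        _SIDECHAIN_TYPE[(residue, atom)] = lj_type


_register("ALA", {"CB": "CT3"})
_register("VAL", {"CB": "CT1", "CG1": "CT3", "CG2": "CT3"})
_register("LEU", {"CB": "CT2", "CG": "CT1", "CD1": "CT3", "CD2": "CT3"})
_register("ILE", {"CB": "CT1", "CG1": "CT2", "CG2": "CT3", "CD1": "CT3", "CD": "CT3"})
_register("MET", {"CB": "CT2", "CG": "CT2", "SD": "S", "CE": "CT3"})
_register("PRO", {"CB": "CT2", "CG": "CT2", "CD": "CT2"})
_register("PHE", {a: "CAro" for a in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")})
_register("TYR", {a: "CAro" for a in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")})
_register("TYR", {"OH": "OH1"})
_register("TRP", {a: "CAro" for a in ("CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")})
_register("TRP", {"NE1": "NH1"})
_register("SER", {"OG": "OH1"})
_register("THR", {"OG1": "OH1", "CG2": "CT3"})
_register("CYS", {"SG": "S"})
_register("ASP", {"CG": "C", "OD1": "O", "OD2": "O"})
_register("ASN", {"CG": "C", "OD1": "O", "ND2": "NH1"})
_register("GLU", {"CG": "CT2", "CD": "C", "OE1": "O", "OE2": "O"})
_register("GLN", {"CG": "CT2", "CD": "C", "OE1": "O", "NE2": "NH1"})
_register("LYS", {"CG": "CT2", "CD": "CT2", "CE": "CT2", "NZ": "NH1"})
_register("ARG", {"CG": "CT2", "CD": "CT2", "NE": "NH1", "CZ": "C", "NH1": "NH1", "NH2": "NH1"})
_register("HIS", {"CG": "CAro", "ND1": "NH1", "CD2": "CAro", "CE1": "CAro", "NE2": "NH1"})

_ELEMENT_FALLBACK = {"C": "CT2", "N": "NH1", "O": "O", "S": "S", "H": "H"}


class UnknownResidueError(ValueError):
    """Raised when an atom's residue is not covered by the group tables."""


def lookup_lj(residue_name: str, atom_name: str, element: str) -> tuple[float, float]:
    """LJ parameters for a protein or surface atom.

    Returns ``(epsilon, rmin_half)`` in kJ/mol and Å.  Surface carbons and
    aromatic rings use the aromatic-carbon type; anything not in the packaged
    sidechain table falls back to a per-element type.
    """
    residue_name = residue_name.upper()
    atom_name = atom_name.upper()
    if residue_name == "GRA":
        lj_type = "CAro"
    elif atom_name in BACKBONE_ATOMS:
        lj_type = {"N": "NH1", "CA": "CT1", "C": "C", "O": "O", "OXT": "O"}[atom_name]
        if residue_name == "GLY" and atom_name == "CA":
            lj_type = "CT2"
    else:
        lj_type = _SIDECHAIN_TYPE.get((residue_name, atom_name))
        if lj_type is None:
            lj_type = _ELEMENT_FALLBACK.get(element.upper())
        if lj_type is None:
            raise KeyError(
                f"no LJ parameters for atom {atom_name!r} (element {element!r}) "
                f"in residue {residue_name!r}"
            )
    eps_kcal, rmin_half = _LJ_TYPES[lj_type]
    return eps_kcal * KCAL_TO_KJ, rmin_half


def classify_atom(residue_name: str, atom_name: str, element: str = "") -> Group:
    """Assign the solvation group of one atom.

    Backbone: Cα and carbonyl C are hydrophobic, carbonyl O and amide N
    hydrophilic (each heavy atom also represents its bonded hydrogens).
    Sidechains follow the per-residue hydrophobic/hydrophilic split, with
    Tyr partitioned atom-by-atom into ring and hydroxyl.
    """
    residue_name = residue_name.upper()
    atom_name = atom_name.upper()
    if residue_name == "GRA":
        return Group.SURFACE_CARBON
    if element.upper() == "H" or atom_name.startswith("H"):
        return Group.EXCLUDED
    if atom_name in BACKBONE_ATOMS:
        if atom_name in ("CA", "C"):
            return Group.HYDROPHOBIC_BACKBONE
        return Group.HYDROPHILIC_BACKBONE
    if residue_name == "TYR":
        if atom_name in TYR_RING_ATOMS:
            return Group.HYDROPHOBIC_SIDECHAIN
        if atom_name in TYR_HYDROXYL_ATOMS:
            return Group.HYDROPHILIC_SIDECHAIN
        raise UnknownResidueError(
            f"ambiguous Tyr atom {atom_name!r}: not in the ring/hydroxyl partition"
        )
    if residue_name in HYDROPHOBIC_RESIDUES:
        return Group.HYDROPHOBIC_SIDECHAIN
    if residue_name in HYDROPHILIC_RESIDUES:
        return Group.HYDROPHILIC_SIDECHAIN
    raise UnknownResidueError(f"unknown residue {residue_name!r} (atom {atom_name!r})")


def sasa_radius_for_element(element: str) -> float:
    try:
        return SASA_RADII[element.upper()]
    except KeyError:
        raise KeyError(f"no SASA radius for element {element!r}") from None


def load_parameter_overrides(path: str | Path) -> dict[tuple[str, str], dict]:
    """Read a per-atom parameter override TSV.

    Columns: residue, atom, epsilon_kJmol, rmin_half_A, radius_A, group.
    A ``*`` residue or atom matches anything; group may be empty to keep the
    default classification.
    """
    overrides: dict[tuple[str, str], dict] = {}
    path = Path(path)
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if fields[0].lower() == "residue":
                continue
            if len(fields) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 tab-separated fields")
            residue, atom, eps, rmin, radius, group = fields[:6]
            entry: dict = {}
            if eps:
                entry["lj_epsilon"] = float(eps)
            if rmin:
                entry["lj_rmin_half"] = float(rmin)
            if radius:
                entry["sasa_radius"] = float(radius)
            if group:
                entry["group"] = Group[group.upper()]
            overrides[(residue.upper(), atom.upper())] = entry
    return overrides
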