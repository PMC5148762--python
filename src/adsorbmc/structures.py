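"""Molecular structures: PDB I/O, group/parameter assignment, ideal helices,
principal axes.

A :class:`MolecularStructure` is a struct-of-arrays container for the atoms of
one rigid molecule.  All coordinates are Å.  Structures are treated as rigid
bodies throughout: poses transform the reference coordinates, never the
internal geometry.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path

import numpy as np

from . import parameters
from .parameters import Group

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "PrincipalAxes",
    "PDBParseError",
    "DegenerateInertiaError",
    "read_pdb",
    "write_pdb",
    "write_group_sidecar",
    "assign_groups",
    "build_alpha_helix",
    "principal_axes",
]


class PDBParseError(ValueError):
    pass


class DegenerateInertiaError(ValueError):
    pass


@dataclasses.dataclass
class AtomRecord:
    """One atom with coordinates, LJ parameters and solvation group."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    position: np.ndarray
    lj_epsilon: float = np.nan
    lj_rmin_half: float = np.nan
    sasa_radius: float = np.nan
    group: Group | None = None


@dataclasses.dataclass
class MolecularStructure:
    """Struct-of-arrays atom container for one rigid molecule."""

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    residue_name: np.ndarray
    residue_index: np.ndarray
    positions: np.ndarray
    lj_epsilon: np.ndarray
    lj_rmin_half: np.ndarray
    sasa_radius: np.ndarray
    group: np.ndarray  # int codes from Group; -1 = unassigned
    unknown_residues: tuple[str, ...] = ()

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def n_residues(self) -> int:
        if self.n_atoms == 0:
            return 0
        change = np.diff(self.residue_index) != 0
        return int(change.sum()) + 1

    @property
    def reference_centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    @property
    def bounding_radius(self) -> float:
        """Max atom distance from the centroid (rotation-invariant)."""
        d = self.positions - self.reference_centroid
        return float(np.sqrt((d * d).sum(axis=1).max()))

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                serial=int(self.serial[i]),
                name=str(self.name[i]),
                element=str(self.element[i]),
                residue_name=str(self.residue_name[i]),
                residue_index=int(self.residue_index[i]),
                position=self.positions[i].copy(),
                lj_epsilon=float(self.lj_epsilon[i]),
                lj_rmin_half=float(self.lj_rmin_half[i]),
                sasa_radius=float(self.sasa_radius[i]),
                group=Group(self.group[i]) if self.group[i] >= 0 else None,
            )
            for i in range(self.n_atoms)
        ]

    def copy(self) -> "MolecularStructure":
        return MolecularStructure(
            serial=self.serial.copy(),
            name=self.name.copy(),
            element=self.element.copy(),
            residue_name=self.residue_name.copy(),
            residue_index=self.residue_index.copy(),
            positions=self.positions.copy(),
            lj_epsilon=self.lj_epsilon.copy(),
            lj_rmin_half=self.lj_rmin_half.copy(),
            sasa_radius=self.sasa_radius.copy(),
            group=self.group.copy(),
            unknown_residues=self.unknown_residues,
        )

    def select(self, mask: np.ndarray) -> "MolecularStructure":
        return MolecularStructure(
            serial=self.serial[mask],
            name=self.name[mask],
            element=self.element[mask],
            residue_name=self.residue_name[mask],
            residue_index=self.residue_index[mask],
            positions=self.positions[mask],
            lj_epsilon=self.lj_epsilon[mask],
            lj_rmin_half=self.lj_rmin_half[mask],
            sasa_radius=self.sasa_radius[mask],
            group=self.group[mask],
            unknown_residues=self.unknown_residues,
        )


def _structure_from_fields(records: list[tuple]) -> MolecularStructure:
    serial, name, element, resn, resi, pos = zip(*records)
    n = len(serial)
    return MolecularStructure(
        serial=np.asarray(serial, dtype=np.int64),
        name=np.asarray(name, dtype="U6"),
        element=np.asarray(element, dtype="U2"),
        residue_name=np.asarray(resn, dtype="U4"),
        residue_index=np.asarray(resi, dtype=np.int64),
        positions=np.asarray(pos, dtype=np.float64).reshape(n, 3),
        lj_epsilon=np.full(n, np.nan),
        lj_rmin_half=np.full(n, np.nan),
        sasa_radius=np.full(n, np.nan),
        group=np.full(n, -1, dtype=np.int64),
    )


def _raise_naming_bad_line(path: Path, exc: Exception) -> None:
    """Scan for the first malformed ATOM record so the error names the line."""
    seen_atoms = False
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            seen_atoms = True
            try:
                int(line[6:11])
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                raise PDBParseError(f"{path}:{ln}: malformed ATOM record") from exc
    if not seen_atoms:
        raise PDBParseError(f"{path}: no ATOM records") from exc
    raise PDBParseError(f"{path}: {exc}") from exc


def read_pdb(path: str | Path, keep_hydrogens: bool = False) -> MolecularStructure:
    """Read ATOM/HETATM records of a PDB file into a structure.

    Parsing is delegated to biotite; the first model is used.  The energy
    model is a heavy-atom model (each heavy atom represents its bonded
    hydrogens), so hydrogens are dropped unless ``keep_hydrogens``.  Residue
    indices are preserved verbatim from the file, so downstream per-residue
    analyses line up with the crystallographic numbering.  Residues outside
    the packaged group tables are kept and reported in ``unknown_residues``.
    """
    from biotite.structure.io import pdb as biotite_pdb

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    try:
        pdb_file = biotite_pdb.PDBFile.read(str(path))
        array = pdb_file.get_structure(model=1, extra_fields=["atom_id"])
    except Exception as exc:  # biotite's error does not name the line
        _raise_naming_bad_line(path, exc)
    if array.array_length() == 0:
        raise PDBParseError(f"{path}: no ATOM records")
    records = []
    for i in range(array.array_length()):
        name = str(array.atom_name[i])
        element = str(array.element[i]).upper() or _element_from_name(name)
        records.append(
            (
                int(array.atom_id[i]),
                name,
                element,
                str(array.res_name[i]),
                int(array.res_id[i]),
                tuple(float(v) for v in array.coord[i]),
            )
        )
    structure = _structure_from_fields(records)
    if not keep_hydrogens:
        structure = structure.select(structure.element != "H")
    known = (
        parameters.HYDROPHOBIC_RESIDUES
        | parameters.HYDROPHILIC_RESIDUES
        | {"TYR", "GRA"}
    )
    unknown = sorted(set(structure.residue_name) - known)
    structure.unknown_residues = tuple(unknown)
    return structure


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA"):
        return stripped[:2].upper()
    return stripped[:1].upper()


def write_pdb(structure: MolecularStructure, path: str | Path,
              positions: np.ndarray | None = None) -> None:
    """Write a structure (optionally with replacement coordinates) as PDB."""
    pos = structure.positions if positions is None else positions
    hetatm = structure.residue_name == "GRA"
    with Path(path).open("w") as fh:
        for i in range(structure.n_atoms):
            record = "HETATM" if hetatm[i] else "ATOM  "
            name = str(structure.name[i])
            name_field = f" {name:<3s}" if len(name) < 4 else name
            fh.write(
                f"{record}{int(structure.serial[i]) % 100000:5d} {name_field}"
                f" {str(structure.residue_name[i]):<4s}A"
                f"{int(structure.residue_index[i]) % 10000:4d}    "
                f"{pos[i, 0]:8.3f}{pos[i, 1]:8.3f}{pos[i, 2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          "
                f"{str(structure.element[i]):>2s}\n"
            )
        fh.write("END\n")


def write_group_sidecar(structure: MolecularStructure, path: str | Path) -> None:
    """Write a (serial, group) TSV companion to an annotated structure."""
    with Path(path).open("w") as fh:
        fh.write("serial\tgroup\n")
        for i in range(structure.n_atoms):
            label = Group(structure.group[i]).name.lower() if structure.group[i] >= 0 else "unassigned"
            fh.write(f"{int(structure.serial[i])}\t{label}\n")


def assign_groups(
    structure: MolecularStructure,
    overrides: dict[tuple[str, str], dict] | None = None,
) -> MolecularStructure:
    """Assign solvation groups, LJ parameters and SASA radii to every atom.

    Raises :class:`~adsorbmc.parameters.UnknownResidueError` for residues
    outside the packaged tables (they are never silently dropped).
    ``overrides`` come from :func:`adsorbmc.parameters.load_parameter_overrides`.
    """
    out = structure.copy()
    for i in range(out.n_atoms):
        resn = str(out.residue_name[i])
        name = str(out.name[i])
        element = str(out.element[i])
        group = parameters.classify_atom(resn, name, element)
        out.group[i] = int(group)
        if group == Group.EXCLUDED:
            out.lj_epsilon[i] = 0.0
            out.lj_rmin_half[i] = parameters.SASA_RADII.get("H", 1.2)
            out.sasa_radius[i] = parameters.SASA_RADII.get("H", 1.2)
        else:
            eps, rmin_half = parameters.lookup_lj(resn, name, element)
            out.lj_epsilon[i] = eps
            out.lj_rmin_half[i] = rmin_half
            out.sasa_radius[i] = parameters.sasa_radius_for_element(element)
        if overrides:
            entry = (
                overrides.get((resn.upper(), name.upper()))
                or overrides.get(("*", name.upper()))
                or overrides.get((resn.upper(), "*"))
            )
            if entry:
                for key, value in entry.items():
                    if key == "group":
                        out.group[i] = int(value)
                    else:
                        getattr(out, key)[i] = value
    return out


# --------------------------------------------------------------------------
# Ideal helix construction
# --------------------------------------------------------------------------

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Backbone internal coordinates of an ideal right-handed alpha helix.
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8

# Sidechain topology: atom -> (ref_a, ref_b, ref_c, bond, angle, dihedral),
# placed by NeRF after N/CA/C/O/CB.  Idealized trans chains; branches offset.
_SIDECHAIN: dict[str, list[tuple[str, str, str, str, float, float, float]]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", "N", "CA", "CB", 1.417, 110.8, 180.0)],
    "CYS": [("SG", "N", "CA", "CB", 1.808, 113.2, 180.0)],
    "THR": [("OG1", "N", "CA", "CB", 1.433, 109.5, 180.0),
            ("CG2", "N", "CA", "CB", 1.521, 110.5, -60.0)],
    "VAL": [("CG1", "N", "CA", "CB", 1.527, 110.5, 180.0),
            ("CG2", "N", "CA", "CB", 1.527, 110.5, -60.0)],
    "LEU": [("CG", "N", "CA", "CB", 1.530, 116.3, 180.0),
            ("CD1", "CA", "CB", "CG", 1.521, 110.7, 60.0),
            ("CD2", "CA", "CB", "CG", 1.521, 110.7, 180.0)],
    "ILE": [("CG1", "N", "CA", "CB", 1.530, 110.4, 180.0),
            ("CG2", "N", "CA", "CB", 1.521, 110.5, -60.0),
            ("CD1", "CA", "CB", "CG1", 1.513, 113.8, 180.0)],
    "MET": [("CG", "N", "CA", "CB", 1.520, 114.1, 180.0),
            ("SD", "CA", "CB", "CG", 1.803, 112.7, 180.0),
            ("CE", "CB", "CG", "SD", 1.791, 100.9, 180.0)],
    "PRO": [("CG", "N", "CA", "CB", 1.492, 104.5, 30.0),
            ("CD", "CA", "CB", "CG", 1.503, 106.1, -35.0)],
    "PHE": [("CG", "N", "CA", "CB", 1.502, 113.8, 180.0),
            ("CD1", "CA", "CB", "CG", 1.391, 120.8, 90.0),
            ("CD2", "CA", "CB", "CG", 1.391, 120.8, -90.0),
            ("CE1", "CB", "CG", "CD1", 1.393, 120.8, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.393, 120.8, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.391, 120.0, 0.0)],
    "TRP": [("CG", "N", "CA", "CB", 1.498, 113.6, 180.0),
            ("CD1", "CA", "CB", "CG", 1.365, 126.9, 90.0),
            ("CD2", "CA", "CB", "CG", 1.433, 126.7, -90.0),
            ("NE1", "CB", "CG", "CD1", 1.374, 110.2, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.409, 107.2, 180.0),
            ("CE3", "CD1", "CG", "CD2", 1.398, 133.9, 180.0),
            ("CZ2", "CG", "CD2", "CE2", 1.394, 122.4, 180.0),
            ("CZ3", "CG", "CD2", "CE3", 1.382, 118.6, 180.0),
            ("CH2", "CD2", "CE3", "CZ3", 1.368, 121.1, 0.0)],
    "ASP": [("CG", "N", "CA", "CB", 1.516, 112.6, 180.0),
            ("OD1", "CA", "CB", "CG", 1.249, 118.4, 0.0),
            ("OD2", "CA", "CB", "CG", 1.249, 118.4, 180.0)],
    "ASN": [("CG", "N", "CA", "CB", 1.516, 112.6, 180.0),
            ("OD1", "CA", "CB", "CG", 1.231, 120.8, 0.0),
            ("ND2", "CA", "CB", "CG", 1.328, 116.4, 180.0)],
    "GLU": [("CG", "N", "CA", "CB", 1.520, 114.1, 180.0),
            ("CD", "CA", "CB", "CG", 1.516, 112.6, 180.0),
            ("OE1", "CB", "CG", "CD", 1.249, 118.4, 0.0),
            ("OE2", "CB", "CG", "CD", 1.249, 118.4, 180.0)],
    "GLN": [("CG", "N", "CA", "CB", 1.520, 114.1, 180.0),
            ("CD", "CA", "CB", "CG", 1.516, 112.6, 180.0),
            ("OE1", "CB", "CG", "CD", 1.231, 120.8, 0.0),
            ("NE2", "CB", "CG", "CD", 1.328, 116.4, 180.0)],
    "LYS": [("CG", "N", "CA", "CB", 1.520, 114.1, 180.0),
            ("CD", "CA", "CB", "CG", 1.522, 111.3, 180.0),
            ("CE", "CB", "CG", "CD", 1.521, 111.3, 180.0),
            ("NZ", "CG", "CD", "CE", 1.489, 112.0, 180.0)],
    "ARG": [("CG", "N", "CA", "CB", 1.520, 114.1, 180.0),
            ("CD", "CA", "CB", "CG", 1.522, 111.3, 180.0),
            ("NE", "CB", "CG", "CD", 1.461, 112.0, 180.0),
            ("CZ", "CG", "CD", "NE", 1.330, 124.2, 180.0),
            ("NH1", "CD", "NE", "CZ", 1.326, 120.0, 0.0),
            ("NH2", "CD", "NE", "CZ", 1.326, 120.0, 180.0)],
    "HIS": [("CG", "N", "CA", "CB", 1.504, 113.8, 180.0),
            ("ND1", "CA", "CB", "CG", 1.378, 122.7, 90.0),
            ("CD2", "CA", "CB", "CG", 1.354, 131.0, -90.0),
            ("CE1", "CB", "CG", "ND1", 1.321, 109.0, 180.0),
            ("NE2", "CB", "CG", "CD2", 1.374, 107.1, 180.0)],
}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd|=bond, angle(b,c,d), dihedral(a,b,c,d)."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_alpha_helix(sequence: str) -> MolecularStructure:
    """Build an ideal alpha-helical peptide from a 1-letter sequence.

    The backbone uses ideal helical dihedrals (phi ≈ −57°, psi ≈ −47°) and
    standard bond geometry; sidechains are placed in idealized extended
    rotamers radiating away from the helix axis.  For alternating
    leucine/lysine sequences this yields an amphipathic helix with all
    leucines on one face.  The result is aligned with the helix axis along
    +z and centroid at the origin, and is bit-reproducible (no randomness).
    """
    sequence = sequence.strip().upper()
    if len(sequence) < 4:
        raise ValueError(f"sequence too short to form a helical turn: {sequence!r}")
    bad = sorted(set(sequence) - set(ONE_TO_THREE))
    if bad:
        raise ValueError(f"invalid residue letter(s): {', '.join(bad)}")

    backbone: list[dict[str, np.ndarray]] = []
    # seed the first three backbone atoms in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    backbone.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, len(sequence)):
        prev = backbone[-1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, _PSI)
        ca = _place_atom(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, _OMEGA)
        c = _place_atom(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, _PHI)
        backbone.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: anti to the next amide N (dihedral psi+180 about CA-C)
    for i, res in enumerate(backbone):
        psi = _PSI if i < len(backbone) - 1 else -40.0
        res["O"] = _place_atom(res["N"], res["CA"], res["C"], _B_C_O, _A_CA_C_O, psi + 180.0)

    records: list[tuple] = []
    serial = 0
    for i, letter in enumerate(sequence):
        resn = ONE_TO_THREE[letter]
        res = dict(backbone[i])
        if resn != "GLY":
            # CB off the backbone with the L-amino-acid improper
            res["CB"] = _place_atom(res["C"], res["N"], res["CA"], 1.530, 110.5, 122.6)
            for name, a, b, c, bond, angle, dihedral in _SIDECHAIN[resn]:
                res[name] = _place_atom(res[a], res[b], res[c], bond, angle, dihedral)
        order = ["N", "CA", "C", "O"] + [nm for nm in res if nm not in ("N", "CA", "C", "O")]
        for name in order:
            serial += 1
            element = name[0] if name[0] in "CNOS" else name[:1]
            records.append((serial, name, element, resn, i + 1, tuple(res[name])))

    structure = _structure_from_fields(records)
    # canonical frame: helix axis (best-fit line through CA atoms) -> +z
    ca_mask = structure.name == "CA"
    ca = structure.positions[ca_mask]
    ca_centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca_centered)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        rot = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - axis @ z) / s**2)
    structure.positions = (structure.positions - structure.positions.mean(axis=0)) @ rot.T
    return structure


# --------------------------------------------------------------------------
# Principal axes
# --------------------------------------------------------------------------

@dataclasses.dataclass
class PrincipalAxes:
    """Orthonormal axes of the gyration tensor, ordered by spatial extent."""

    axis1: np.ndarray
    axis2: np.ndarray
    axis3: np.ndarray
    eigenvalues: np.ndarray  # Å², descending

    @property
    def matrix(self) -> np.ndarray:
        """Rows = axis1, axis2, axis3."""
        return np.vstack([self.axis1, self.axis2, self.axis3])


def principal_axes(
    structure: MolecularStructure | np.ndarray,
    reference: np.ndarray | None = None,
) -> PrincipalAxes:
    """Principal axes of the coordinate gyration tensor about the centroid.

    Axes are ordered by descending eigenvalue.  Signs are fixed
    deterministically: each of the two major axes is flipped to have a
    non-negative dot product with a body-fixed reference vector (centroid to
    the N-terminal Cα, falling back to the first atom; exact ties fall back
    to +z), and axis3 completes a right-handed triad.  The body-fixed
    reference makes the convention rotation-equivariant, so orientation
    angles derived from the axes are single-valued along a trajectory.
    """
    if isinstance(structure, MolecularStructure):
        pos = structure.positions
        if reference is None:
            ca = np.nonzero(structure.name == "CA")[0]
            anchor = pos[ca[0]] if len(ca) else pos[0]
            reference = anchor - pos.mean(axis=0)
    else:
        pos = np.asarray(structure, dtype=float)
        if reference is None:
            reference = pos[0] - pos.mean(axis=0)
    if pos.shape[0] < 3:
        raise DegenerateInertiaError("need at least 3 atoms for principal axes")
    centered = pos - pos.mean(axis=0)
    gyr = centered.T @ centered / pos.shape[0]
    evals, evecs = np.linalg.eigh(gyr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    axes = evecs[:, order].T
    if evals[0] <= 0 or evals[1] / evals[0] < 1e-10:
        raise DegenerateInertiaError("degenerate inertia: atoms are (near-)collinear")
    zhat = np.array([0.0, 0.0, 1.0])
    for k in range(2):
        d = axes[k] @ reference
        if abs(d) < 1e-9:
            d = axes[k] @ zhat
        if d < 0:
            axes[k] = -axes[k]
    axes[2] = np.cross(axes[0], axes[1])
    return PrincipalAxes(axis1=axes[0], axis2=axes[1], axis3=axes[2], eigenvalues=evals)
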