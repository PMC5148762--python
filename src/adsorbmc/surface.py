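"""Periodic graphene surface: honeycomb lattice, periodic images, patches.

The adsorbing surface is a single frozen graphene sheet in the z = 0 plane
with outward normal +z.  The sheet is periodic in x and y, so any geometry
near the protein can be generated on demand by tiling the two-atom primitive
cell; a finite simulation box (``box_a`` x ``box_b``) is kept only as the
repeat unit for minimum-image arithmetic.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import parameters
from .constants import GRAPHENE_BOND_LENGTH
from .parameters import Group
from .structures import AtomRecord, MolecularStructure, _structure_from_fields, write_pdb

__all__ = ["SurfaceModel", "build_graphene", "surface_patch"]


@dataclasses.dataclass
class SurfaceModel:
    """A periodic single-layer graphene lattice at z = 0, normal +z."""

    structure: MolecularStructure
    box_a: np.ndarray
    box_b: np.ndarray
    bond_length: float
    n_cells_x: int
    n_cells_y: int
    plane_z: float = 0.0

    @property
    def normal(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])

    @property
    def atoms(self) -> list[AtomRecord]:
        return self.structure.atoms

    @property
    def primitive_a(self) -> np.ndarray:
        return self.box_a / self.n_cells_x

    @property
    def primitive_b(self) -> np.ndarray:
        return self.box_b / self.n_cells_y

    @property
    def basis_xy(self) -> np.ndarray:
        """xy offsets of the two basis atoms within the primitive cell."""
        return np.array([
            [0.0, 0.0],
            ((self.primitive_a + self.primitive_b) / 3.0)[:2],
        ])

    @property
    def cell_matrix(self) -> np.ndarray:
        """Columns = primitive lattice vectors (2x2, xy)."""
        return np.column_stack([self.primitive_a[:2], self.primitive_b[:2]])

    @property
    def atom_density(self) -> float:
        """Atoms per Å² (2 per primitive cell)."""
        return 2.0 / abs(np.linalg.det(self.cell_matrix))

    def snap_to_lattice(self, point_xy: np.ndarray) -> np.ndarray:
        """Nearest primitive-lattice translation to ``point_xy`` (shape (2,))."""
        frac = np.linalg.solve(self.cell_matrix, np.asarray(point_xy, dtype=float))
        return self.cell_matrix @ np.round(frac)

    def patch_positions(self, center_xy: np.ndarray, radius: float) -> np.ndarray:
        """Positions (n, 3) of all lattice atoms (with periodic images) whose
        xy distance to ``center_xy`` is at most ``radius``.  Deterministic
        ordering by (cell index i, j, basis atom)."""
        if radius <= 0:
            raise ValueError("footprint_radius must be positive")
        center = np.asarray(center_xy, dtype=float)[:2]
        m = self.cell_matrix
        # integer range large enough to cover the disc from any fractional offset
        inv = np.linalg.inv(m)
        corners = np.array([[radius, radius], [radius, -radius],
                            [-radius, radius], [-radius, -radius]])
        frac_c = inv @ center
        span = np.abs(inv @ corners.T).max(axis=1)
        i_range = np.arange(int(np.floor(frac_c[0] - span[0])) - 1,
                            int(np.ceil(frac_c[0] + span[0])) + 2)
        j_range = np.arange(int(np.floor(frac_c[1] - span[1])) - 1,
                            int(np.ceil(frac_c[1] + span[1])) + 2)
        ii, jj = np.meshgrid(i_range, j_range, indexing="ij")
        origins = np.stack([ii.ravel(), jj.ravel()], axis=1) @ m.T  # (cells, 2)
        basis = self.basis_xy
        pts = (origins[:, None, :] + basis[None, :, :]).reshape(-1, 2)
        keep = np.linalg.norm(pts - center, axis=1) <= radius
        xy = pts[keep]
        out = np.zeros((len(xy), 3))
        out[:, :2] = xy
        out[:, 2] = self.plane_z
        return out

    def min_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance of each point to the nearest surface atom (infinite lattice)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        m = self.cell_matrix
        inv = np.linalg.inv(m)
        best = np.full(len(pts), np.inf)
        dz2 = (pts[:, 2] - self.plane_z) ** 2
        for b in self.basis_xy:
            rel = pts[:, :2] - b
            frac = rel @ inv.T
            base = np.round(frac)
            for di in (-1.0, 0.0, 1.0):
                for dj in (-1.0, 0.0, 1.0):
                    offs = (base + [di, dj]) @ m.T
                    d2 = ((rel - offs) ** 2).sum(axis=1) + dz2
                    best = np.minimum(best, d2)
        return np.sqrt(best)

    def to_files(self, pdb_path: str | Path, json_path: str | Path | None = None) -> None:
        """Write the lattice as PDB (HETATM, residue GRA) + JSON box sidecar."""
        write_pdb(self.structure, pdb_path)
        if json_path is not None:
            with Path(json_path).open("w") as fh:
                json.dump(
                    {
                        "box_a": self.box_a.tolist(),
                        "box_b": self.box_b.tolist(),
                        "bond_length": self.bond_length,
                        "n_cells_x": self.n_cells_x,
                        "n_cells_y": self.n_cells_y,
                        "plane_z": self.plane_z,
                    },
                    fh,
                    indent=1,
                )


def build_graphene(
    n_cells_x: int,
    n_cells_y: int,
    bond_length: float = GRAPHENE_BOND_LENGTH,
) -> SurfaceModel:
    """Build an ``n_cells_x`` x ``n_cells_y`` periodic graphene sheet.

    Two carbon atoms per primitive cell, all at z = 0, carrying the
    surface-carbon solvation group and aromatic-carbon LJ parameters.
    Carbons are neutral, so the model has no electrostatics.
    """
    if n_cells_x < 1 or n_cells_y < 1:
        raise ValueError("n_cells_x and n_cells_y must be >= 1")
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    a = np.sqrt(3.0) * bond_length
    prim_a = np.array([a, 0.0, 0.0])
    prim_b = np.array([a / 2.0, a * np.sqrt(3.0) / 2.0, 0.0])
    basis = [np.zeros(3), (prim_a + prim_b) / 3.0]
    records = []
    serial = 0
    for i in range(n_cells_x):
        for j in range(n_cells_y):
            origin = i * prim_a + j * prim_b
            for b in basis:
                serial += 1
                p = origin + b
                records.append((serial, "C", "C", "GRA", 1, tuple(p)))
    structure = _structure_from_fields(records)
    eps, rmin_half = parameters.lookup_lj("GRA", "C", "C")
    structure.lj_epsilon[:] = eps
    structure.lj_rmin_half[:] = rmin_half
    structure.sasa_radius[:] = parameters.sasa_radius_for_element("C")
    structure.group[:] = int(Group.SURFACE_CARBON)
    return SurfaceModel(
        structure=structure,
        box_a=n_cells_x * prim_a,
        box_b=n_cells_y * prim_b,
        bond_length=bond_length,
        n_cells_x=n_cells_x,
        n_cells_y=n_cells_y,
    )


def surface_patch(
    surface: SurfaceModel,
    footprint_center: np.ndarray,
    footprint_radius: float,
) -> list[AtomRecord]:
    """All lattice atoms (including periodic images) within ``footprint_radius``
    (xy distance) of ``footprint_center``, as fully parameterized records."""
    positions = surface.patch_positions(np.asarray(footprint_center)[:2], footprint_radius)
    eps = float(surface.structure.lj_epsilon[0])
    rmin_half = float(surface.structure.lj_rmin_half[0])
    radius = float(surface.structure.sasa_radius[0])
    return [
        AtomRecord(
            serial=i + 1,
            name="C",
            element="C",
            residue_name="GRA",
            residue_index=1,
            position=positions[i].copy(),
            lj_epsilon=eps,
            lj_rmin_half=rmin_half,
            sasa_radius=radius,
            group=Group.SURFACE_CARBON,
        )
        for i in range(len(positions))
    ]
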