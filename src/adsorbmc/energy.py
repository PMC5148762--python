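"""Protein-surface energy model: Lennard-Jones VDW + SASA-weighted solvation.

The total energy of a posed protein over the graphene sheet is

    E = E_vdw + E_solv,
    E_vdw  = sum over protein-surface pairs within the cutoff of the 12-6 form
             eps [(Rmin/r)^12 - 2 (Rmin/r)^6]   (CHARMM combining rules),
    E_solv = sum over atoms of sigma(group) * SASA(atom),

where SASA is a Shrake-Rupley area with a 1.4 Å probe evaluated over the
union of the posed protein and a patch of surface atoms underneath it.  The
patch is a rigid translate of a fixed template snapped to the lattice, so
its far-field contribution is a pose-independent constant that cancels in
the energy differences the Metropolis sampler consumes.  Burying hydrophobic
area (protein sidechains against the hydrophobic surface carbons) lowers
E_solv; burying hydrophilic area raises it.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._kernels import (
    evaluate_pose_kernel,
    neighbor_csr,
    pair_scan,
    sasa_areas,
    symmetric_sphere_points,
)
from .constants import (
    DEFAULT_PROBE_RADIUS,
    DEFAULT_SASA_POINTS,
    DEFAULT_SASA_SMOOTHING,
    DEFAULT_VDW_CUTOFF,
)
from .parameters import DEFAULT_SIGMA, Group
from .pose import RigidPose
from .structures import AtomRecord, MolecularStructure
from .surface import SurfaceModel

__all__ = [
    "SigmaTable",
    "EnergyComponents",
    "EnergyConfig",
    "EnergyModel",
    "lj_pair_energy",
    "vdw_energy",
    "sasa",
    "solvation_energy",
    "total_energy",
]


class SigmaTable:
    """Surface tensions per solvation group, kJ/(mol*Å²)."""

    def __init__(self, overrides: dict[Group, float] | None = None):
        table = dict(DEFAULT_SIGMA)
        if overrides:
            table.update(overrides)
        self._table = table

    def __getitem__(self, group: Group) -> float:
        if group == Group.EXCLUDED:
            return 0.0
        try:
            return self._table[Group(group)]
        except KeyError:
            raise KeyError(f"no surface tension entry for group {Group(group).name}") from None

    def per_atom(self, groups: np.ndarray) -> np.ndarray:
        """sigma value for each atom given integer group codes."""
        groups = np.asarray(groups)
        if (groups < 0).any():
            raise ValueError("unassigned group encountered; run assign_groups first")
        return np.array([self[Group(g)] for g in groups])


@dataclasses.dataclass(frozen=True)
class EnergyComponents:
    vdw: float
    solvation: float

    @property
    def total(self) -> float:
        return self.vdw + self.solvation


@dataclasses.dataclass
class EnergyConfig:
    probe_radius: float = DEFAULT_PROBE_RADIUS
    vdw_cutoff: float = DEFAULT_VDW_CUTOFF
    sasa_points: int = DEFAULT_SASA_POINTS
    #: width (Å) of the smoothstep band replacing the binary point-burial
    #: test inside the sampler's energy; 0 recovers exact Shrake-Rupley.
    #: The large surface tensions make the discrete landscape rough on the
    #: scale of tens of kBT, which freezes a Metropolis chain; the smoothed
    #: indicator restores a continuous landscape without changing where its
    #: minima lie.
    sasa_smoothing: float = DEFAULT_SASA_SMOOTHING
    sigma: SigmaTable = dataclasses.field(default_factory=SigmaTable)

    def patch_margin(self, max_radius: float) -> float:
        """xy margin beyond the protein's bounding circle inside which surface
        atoms can still occlude (or be occluded by) protein atoms."""
        return 2.0 * self.probe_radius + 2.0 * max_radius + self.sasa_smoothing + 2.0


def lj_pair_energy(
    r: float,
    eps_i: float,
    eps_j: float,
    rmin_half_i: float,
    rmin_half_j: float,
) -> float:
    """12-6 Lennard-Jones pair energy, CHARMM convention.

    ``E = eps [(Rmin/r)^12 - 2 (Rmin/r)^6]`` with ``eps = sqrt(eps_i eps_j)``
    and ``Rmin = rmin_half_i + rmin_half_j``; the minimum is ``-eps`` at
    ``r = Rmin``.
    """
    if r <= 0:
        raise ValueError("pair distance must be positive (coincident atoms signal a broken pose)")
    eps = np.sqrt(eps_i * eps_j)
    s6 = ((rmin_half_i + rmin_half_j) / r) ** 6
    return eps * (s6 * s6 - 2.0 * s6)


def _atoms_to_arrays(atoms) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(atoms, MolecularStructure):
        return atoms.positions, atoms.sasa_radius, atoms.group
    if len(atoms) and isinstance(atoms[0], AtomRecord):
        pos = np.array([a.position for a in atoms], dtype=float)
        rad = np.array([a.sasa_radius for a in atoms], dtype=float)
        grp = np.array(
            [int(a.group) if a.group is not None else -1 for a in atoms], dtype=np.int64
        )
        return pos, rad, grp
    raise TypeError("atoms must be a MolecularStructure or a list of AtomRecord")


def sasa(
    atoms,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SASA_POINTS,
) -> np.ndarray:
    """Shrake-Rupley solvent accessible surface area per atom, Å².

    Exact binary point-burial test on a fixed deterministic sphere point
    set, so repeated calls are bit-identical.  ``atoms`` may be a structure
    or an AtomRecord list.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    pos, rad, _ = _atoms_to_arrays(atoms)
    if np.isnan(rad).any():
        raise ValueError("atoms lack SASA radii; run assign_groups first")
    points = symmetric_sphere_points(n_sphere_points)
    mask = np.ones(len(pos), dtype=bool)
    return sasa_areas(pos, rad, probe_radius, points, mask)


def solvation_energy(areas: np.ndarray, groups: np.ndarray, sigma: SigmaTable) -> float:
    """sum over atoms of sigma(group) * area; excluded atoms contribute 0."""
    areas = np.asarray(areas, dtype=float)
    groups = np.asarray(groups)
    if areas.shape != groups.shape:
        raise ValueError("areas and groups must be aligned")
    return float(areas @ sigma.per_atom(groups))


class EnergyModel:
    """Cached evaluator of the total energy for poses of one protein.

    Precomputes the surface patch template (a disc of lattice atoms large
    enough for both the VDW cutoff and SASA occlusion range around the
    protein) and its baseline per-atom areas.  At each pose the patch is the
    template translated by the lattice vector nearest the protein centroid,
    so patch geometry — and therefore the patch's far-field solvation
    constant — is identical across poses.
    """

    def __init__(
        self,
        protein: MolecularStructure,
        surface: SurfaceModel,
        config: EnergyConfig | None = None,
    ):
        if (protein.group < 0).any():
            raise ValueError("protein has unassigned groups; run assign_groups first")
        self.protein = protein
        self.surface = surface
        self.config = config or EnergyConfig()
        self._ref_positions = protein.positions.copy()
        self._centroid = protein.reference_centroid.copy()
        max_rad = float(protein.sasa_radius.max())
        margin = self.config.patch_margin(max_rad)
        patch_radius = protein.bounding_radius + max(self.config.vdw_cutoff, margin) + 2.0
        self._patch_template = surface.patch_positions(np.zeros(2), patch_radius)
        n_s = len(self._patch_template)
        s = surface.structure
        self._s_eps = np.full(n_s, float(s.lj_epsilon[0]))
        self._s_rmin_half = np.full(n_s, float(s.lj_rmin_half[0]))
        self._s_rad = np.full(n_s, float(s.sasa_radius[0]))
        self._s_sigma = self.config.sigma[Group.SURFACE_CARBON]
        self._p_sigma = self.config.sigma.per_atom(protein.group)
        self._points = symmetric_sphere_points(self.config.sasa_points)
        base_mask = np.ones(n_s, dtype=bool)
        self._base_areas = sasa_areas(
            self._patch_template, self._s_rad, self.config.probe_radius,
            self._points, base_mask, self.config.sasa_smoothing,
        )
        self._base_solvation = self._s_sigma * float(self._base_areas.sum())
        # rigid-body occlusion topology: constant across poses
        self._p_nb_idx, self._p_nb_ptr = neighbor_csr(
            self._ref_positions, protein.sasa_radius, self.config.probe_radius,
            self.config.sasa_smoothing,
        )
        self._s_nb_idx, self._s_nb_ptr = neighbor_csr(
            self._patch_template, self._s_rad, self.config.probe_radius,
            self.config.sasa_smoothing,
        )

    def evaluate(self, pose: RigidPose) -> tuple[EnergyComponents, float]:
        """Energy components and minimum protein-surface distance for a pose."""
        p = self.protein
        ppos = pose.apply(self._ref_positions, self._centroid)
        shift = self.surface.snap_to_lattice(ppos.mean(axis=0)[:2])
        spos = self._patch_template + np.array([shift[0], shift[1], 0.0])
        # protein test points are body-fixed: rotating them with the pose makes
        # point-sampled SASA exactly invariant under rigid rotations of the
        # protein (the intramolecular burial pattern never changes)
        p_points = pose.rotation.apply(self._points)
        vdw, min_dist, p_areas, s_areas, flags, coincident = evaluate_pose_kernel(
            ppos, p.lj_epsilon, p.lj_rmin_half, p.sasa_radius,
            self._p_nb_idx, self._p_nb_ptr,
            spos, self._s_eps, self._s_rmin_half, self._s_rad,
            self._s_nb_idx, self._s_nb_ptr,
            self.config.vdw_cutoff, self.config.probe_radius,
            self.config.sasa_smoothing, p_points, self._points,
        )
        if coincident:
            raise ValueError("protein atom exactly coincident with a surface atom")
        solv = float(p_areas @ self._p_sigma)
        solv += self._s_sigma * float(s_areas[flags].sum())
        # unflagged surface atoms keep their pose-independent baseline area
        solv += self._base_solvation - self._s_sigma * float(self._base_areas[flags].sum())
        return EnergyComponents(vdw=float(vdw), solvation=solv), float(min_dist)


def vdw_energy(
    protein: MolecularStructure,
    pose: RigidPose,
    surface: SurfaceModel,
    cutoff: float = DEFAULT_VDW_CUTOFF,
) -> float:
    """Lennard-Jones energy of a posed protein over the periodic surface.

    Sums :func:`lj_pair_energy` over all protein-surface pairs within the
    cutoff, with surface periodic images included (equivalent to the
    minimum-image convention on the infinite sheet).  Protein intramolecular
    terms are a rigid-body constant and excluded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ppos = pose.apply(protein.positions, protein.reference_centroid)
    centroid = ppos.mean(axis=0)
    extent = np.linalg.norm((ppos - centroid)[:, :2], axis=1).max() if len(ppos) else 0.0
    spos = surface.patch_positions(centroid[:2], extent + cutoff + 1.0)
    n_s = len(spos)
    s = surface.structure
    vdw, _, _, coincident = pair_scan(
        ppos, protein.lj_epsilon, protein.lj_rmin_half, protein.sasa_radius,
        spos,
        np.full(n_s, float(s.lj_epsilon[0])),
        np.full(n_s, float(s.lj_rmin_half[0])),
        np.full(n_s, float(s.sasa_radius[0])),
        cutoff, 0.0,
    )
    if coincident:
        raise ValueError("protein atom exactly coincident with a surface atom")
    return float(vdw)


def total_energy(
    protein: MolecularStructure,
    pose: RigidPose,
    surface: SurfaceModel,
    config: EnergyConfig | None = None,
) -> EnergyComponents:
    """Total energy (VDW + solvation) of a posed protein-surface system.

    Convenience wrapper building a one-shot :class:`EnergyModel`; sampling
    loops should hold an :class:`EnergyModel` to reuse the patch template.
    """
    model = EnergyModel(protein, surface, config)
    components, _ = model.evaluate(pose)
    return components
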