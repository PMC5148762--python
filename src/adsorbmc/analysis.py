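"""Orientation, contact and free-energy analyses of sampled trajectories.

Adsorption orientation is parameterized by the angles (phi, psi) between the
two largest principal axes of the protein and the surface normal (+z).  A
free-energy landscape over orientation bins follows from the sampled
histogram as ``G = -kB T ln N``; its minima are the preferred adsorbed
orientations.  Per-residue contact profiles report how often each residue
touches the surface among adsorbed frames.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .constants import DEFAULT_TEMPERATURE, KB
from .mc import Trajectory
from .pose import RigidPose
from .structures import MolecularStructure, PrincipalAxes, principal_axes
from .surface import SurfaceModel

__all__ = [
    "OrientationDescriptor",
    "FreeEnergyMap",
    "ContactProfile",
    "orientation_angles",
    "trajectory_orientations",
    "contact_profile",
    "free_energy_map",
    "find_minima",
    "relative_rotation",
]


@dataclasses.dataclass(frozen=True)
class OrientationDescriptor:
    """Angles (degrees, [0, 180]) of the two major principal axes vs +z."""

    phi: float
    psi: float


@dataclasses.dataclass
class FreeEnergyMap:
    """Binned orientation histogram and its free-energy surface.

    ``counts[i, j]`` is the number of frames with phi in bin i and psi in
    bin j; ``G = -kB T ln(counts)`` on populated bins and masked elsewhere.
    """

    bin_width: float
    counts: np.ndarray
    G: np.ma.MaskedArray
    temperature: float

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(0.0, 180.0 + self.bin_width / 2, self.bin_width)

    def to_dataframe(self) -> pd.DataFrame:
        edges = self.bin_edges[:-1]
        rows = []
        for i, lo_phi in enumerate(edges):
            for j, lo_psi in enumerate(edges):
                rows.append(
                    {
                        "phi_bin_lo": lo_phi,
                        "psi_bin_lo": lo_psi,
                        "count": int(self.counts[i, j]),
                        "G_kJmol": float(self.G[i, j]) if not self.G.mask[i, j] else np.nan,
                    }
                )
        return pd.DataFrame(rows)


@dataclasses.dataclass
class ContactProfile:
    """Fraction of adsorbed frames in which each residue touches the surface."""

    residue_index: np.ndarray
    residue_name: np.ndarray
    ratio: np.ndarray
    n_adsorbed_frames: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_index": self.residue_index,
                "residue_name": self.residue_name,
                "ratio": self.ratio,
            }
        )


def orientation_angles(
    protein: MolecularStructure,
    pose: RigidPose,
    axes: PrincipalAxes | None = None,
) -> OrientationDescriptor:
    """(phi, psi) of a posed structure: angles of the rotated, sign-fixed
    axis1/axis2 against +z, in degrees within [0, 180]."""
    if axes is None:
        axes = principal_axes(protein)
    rot = pose.rotation
    a1 = rot.apply(axes.axis1)
    a2 = rot.apply(axes.axis2)
    phi = float(np.degrees(np.arccos(np.clip(a1[2], -1.0, 1.0))))
    psi = float(np.degrees(np.arccos(np.clip(a2[2], -1.0, 1.0))))
    return OrientationDescriptor(phi=phi, psi=psi)


def trajectory_orientations(
    trajectory: Trajectory, protein: MolecularStructure
) -> np.ndarray:
    """(n_frames, 2) array of (phi, psi) along a trajectory (vectorized)."""
    axes = principal_axes(protein)
    rots = Rotation.from_quat(trajectory.quaternions)
    a1 = rots.apply(axes.axis1)
    a2 = rots.apply(axes.axis2)
    phi = np.degrees(np.arccos(np.clip(a1[:, 2], -1.0, 1.0)))
    psi = np.degrees(np.arccos(np.clip(a2[:, 2], -1.0, 1.0)))
    return np.column_stack([phi, psi])


def contact_profile(
    trajectory: Trajectory,
    protein: MolecularStructure,
    surface: SurfaceModel,
    cutoff: float = 6.0,
) -> ContactProfile:
    """Per-residue surface-contact ratios over the adsorbed frames.

    A residue is in contact in a frame when any of its atoms lies within
    ``cutoff`` of any surface atom (atom-to-atom, minimum image on the
    infinite lattice).  The denominator counts frames where *any* protein
    atom is within ``cutoff``; frames with the protein fully away from the
    surface do not enter the ratio.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    res_ids, first_idx = np.unique(protein.residue_index, return_index=True)
    res_names = protein.residue_name[first_idx]
    atom_res = np.searchsorted(res_ids, protein.residue_index)
    centroid = protein.reference_centroid
    n_res = len(res_ids)
    contact_frames = np.zeros(n_res, dtype=np.int64)
    n_adsorbed = 0
    rots = Rotation.from_quat(trajectory.quaternions)
    for k in range(len(trajectory)):
        posed = rots[k].apply(protein.positions - centroid) + centroid + trajectory.translations[k]
        dist = surface.min_distance(posed)
        touching = dist <= cutoff
        if not touching.any():
            continue
        n_adsorbed += 1
        touched_res = np.unique(atom_res[touching])
        contact_frames[touched_res] += 1
    if n_adsorbed == 0:
        raise ValueError("no adsorbed frames within the contact cutoff")
    return ContactProfile(
        residue_index=res_ids,
        residue_name=res_names,
        ratio=contact_frames / n_adsorbed,
        n_adsorbed_frames=n_adsorbed,
    )


def merge_contact_profiles(profiles: list[ContactProfile]) -> ContactProfile:
    """Pool contact statistics from several runs (frame-weighted)."""
    if not profiles:
        raise ValueError("no profiles to merge")
    base = profiles[0]
    counts = np.zeros_like(base.ratio)
    total = 0
    for p in profiles:
        if not np.array_equal(p.residue_index, base.residue_index):
            raise ValueError("profiles cover different residue sets")
        counts += p.ratio * p.n_adsorbed_frames
        total += p.n_adsorbed_frames
    return ContactProfile(
        residue_index=base.residue_index.copy(),
        residue_name=base.residue_name.copy(),
        ratio=counts / total,
        n_adsorbed_frames=total,
    )


def free_energy_map(
    orientations: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    bin_width: float = 10.0,
) -> FreeEnergyMap:
    """Histogram (phi, psi) on ``bin_width``-degree bins and convert counts to
    free energies ``G = -kB T ln N``; empty bins are masked, not infinite."""
    orientations = np.atleast_2d(np.asarray(orientations, dtype=float))
    if orientations.size == 0:
        raise ValueError("need at least one orientation")
    if not np.isclose(180.0 / bin_width, round(180.0 / bin_width)):
        raise ValueError("bin_width must divide 180")
    edges = np.arange(0.0, 180.0 + bin_width / 2, bin_width)
    counts, _, _ = np.histogram2d(
        orientations[:, 0], orientations[:, 1], bins=(edges, edges)
    )
    counts = counts.astype(np.int64)
    with np.errstate(divide="ignore"):
        g = -KB * temperature * np.log(counts.astype(float))
    G = np.ma.masked_array(g, mask=counts == 0)
    return FreeEnergyMap(bin_width=bin_width, counts=counts, G=G, temperature=temperature)


def find_minima(fe_map: FreeEnergyMap, depth_threshold: float | None = None) -> list[tuple[int, int]]:
    """Local minima of G over the 8-neighborhood of populated bins.

    Only minima deeper than ``depth_threshold`` (default 1 kB T) below the
    median G of populated bins are kept.  Ordered by depth (deepest first);
    ties broken lexicographically by (phi bin, psi bin).
    """
    if depth_threshold is None:
        depth_threshold = KB * fe_map.temperature
    counts = fe_map.counts
    if counts.sum() == 0:
        raise ValueError("map has no populated bin")
    G = fe_map.G
    populated = ~G.mask
    if populated.sum() == 1:
        i, j = np.argwhere(populated)[0]
        return [(int(i), int(j))]
    median = float(np.ma.median(G))
    n_phi, n_psi = counts.shape
    minima = []
    for i in range(n_phi):
        for j in range(n_psi):
            if not populated[i, j]:
                continue
            g = G[i, j]
            if g >= median - depth_threshold:
                continue
            is_min = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ni, nj = i + di, j + dj
                    if 0 <= ni < n_phi and 0 <= nj < n_psi and populated[ni, nj]:
                        if G[ni, nj] < g:
                            is_min = False
            if is_min:
                minima.append((i, j))
    minima.sort(key=lambda b: (float(G[b[0], b[1]]), b[0], b[1]))
    return minima


def relative_rotation(
    pose_a: RigidPose, pose_b: RigidPose, axes: PrincipalAxes
) -> dict:
    """Decompose the rotation taking pose_a to pose_b.

    Returns the total rotation angle and axis of ``R_b R_a^-1`` plus the
    twist angle about the structure's second principal axis (expressed in the
    pose_a frame), all in degrees within [0, 180].  Symmetric:
    ``angle(a->b) == angle(b->a)``.
    """
    rel = pose_b.rotation * pose_a.rotation.inv()
    rotvec = rel.as_rotvec()
    total = np.degrees(np.linalg.norm(rotvec))
    if total > 180.0:
        total = 360.0 - total
    axis2_lab = pose_a.rotation.apply(axes.axis2)
    q = rel.as_quat()
    v, w = q[:3], q[3]
    # swing-twist decomposition: twist quaternion about axis2
    proj = float(v @ axis2_lab)
    twist = 2.0 * np.degrees(np.arctan2(abs(proj), abs(w))) if (proj, w) != (0.0, 0.0) else 0.0
    if twist > 180.0:
        twist = 360.0 - twist
    axis = rotvec / np.linalg.norm(rotvec) if np.linalg.norm(rotvec) > 0 else np.zeros(3)
    return {
        "total_angle": float(total),
        "axis": axis,
        "angle_about_axis2": float(twist),
    }
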