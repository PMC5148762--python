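"""Metropolis Monte Carlo sampling of rigid-body protein poses on a surface.

Each step proposes a symmetric random rigid-body move (uniform translation
increment, uniform-axis/uniform-angle rotation increment about the protein
centroid), evaluates the total energy, and accepts with probability
``min(1, exp(-dE/kBT))``.  Only accepted poses are logged; a run finishes
after a target number of accepted moves.  Chains whose protein drifts away
from the surface and does not return are flagged as escaped so they can be
excluded from analysis, mirroring how simulations that desorb permanently
are discarded.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .constants import DEFAULT_TEMPERATURE, KB
from .energy import EnergyComponents, EnergyConfig, EnergyModel
from .pose import RigidPose
from .structures import MolecularStructure, principal_axes
from .surface import SurfaceModel

__all__ = [
    "MCConfig",
    "TrajectoryFrame",
    "Trajectory",
    "StallError",
    "propose_move",
    "metropolis_accept",
    "run_mc",
    "detect_escape",
    "adsorbed_start_pose",
    "face_down_pose",
]


class StallError(RuntimeError):
    """No proposal was accepted within the configured proposal budget."""


@dataclasses.dataclass
class MCConfig:
    """Sampler settings.

    The proposal kernel is a symmetric two-class mixture.  Small moves
    (``max_translation_step`` / ``max_rotation_step``) sample the steep
    adsorbed basins; their defaults are calibrated to give roughly 30-60%
    acceptance for an adsorbed amphipathic helix, whose energy varies by
    thousands of kJ/mol per Å under the surface-tension scale of the scoring
    model.  Large moves (``large_*``, drawn with ``large_move_probability``)
    are full reorientations with Å-scale displacements; they are almost
    always rejected at equilibrium but are what carries the chain across
    orientation barriers (e.g. the lysines-down to leucines-down flip) that
    small steps could never cross.  Both classes are symmetric, so plain
    Metropolis acceptance is correct.
    """

    temperature: float = DEFAULT_TEMPERATURE
    max_translation_step: float = 0.01
    max_rotation_step: float = 0.05  # degrees
    large_move_probability: float = 0.15
    large_translation_step: float = 3.0
    large_rotation_step: float = 180.0  # degrees
    target_accepted_moves: int = 10_000
    seed: int = 0
    escape_distance: float = 15.0
    escape_patience: int = 500  # accepted frames
    stall_proposal_budget: int = 200_000
    energy: EnergyConfig = dataclasses.field(default_factory=EnergyConfig)

    def __post_init__(self) -> None:
        if self.target_accepted_moves < 1:
            raise ValueError("target_accepted_moves must be >= 1")
        if self.max_translation_step < 0 or self.max_rotation_step < 0:
            raise ValueError("step sizes must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclasses.dataclass
class TrajectoryFrame:
    accepted_index: int
    pose: RigidPose
    energy: EnergyComponents
    min_surface_distance: float


class Trajectory:
    """Accepted poses of one chain, with energies and surface distances.

    ``multiplicity[i]`` is the number of Markov-chain steps frame i persisted
    (1 + the rejected proposals that followed it).  Frame streams indexed by
    accepted moves match the accepted-orientation bookkeeping of the
    sampling protocol; expectation values over the Boltzmann distribution
    must weight each frame by its multiplicity (the textbook Metropolis
    estimator, which re-counts the current state on rejection).
    """

    def __init__(
        self,
        translations: np.ndarray,
        quaternions: np.ndarray,
        vdw: np.ndarray,
        solvation: np.ndarray,
        min_surface_distance: np.ndarray,
        n_proposals: int = 0,
        config: MCConfig | None = None,
        multiplicity: np.ndarray | None = None,
    ):
        self.translations = np.asarray(translations, dtype=float).reshape(-1, 3)
        self.quaternions = np.asarray(quaternions, dtype=float).reshape(-1, 4)
        self.vdw = np.asarray(vdw, dtype=float)
        self.solvation = np.asarray(solvation, dtype=float)
        self.min_surface_distance = np.asarray(min_surface_distance, dtype=float)
        self.n_proposals = n_proposals
        self.config = config
        if multiplicity is None:
            multiplicity = np.ones(len(self.vdw), dtype=np.int64)
        self.multiplicity = np.asarray(multiplicity, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.vdw)

    @property
    def total(self) -> np.ndarray:
        return self.vdw + self.solvation

    def pose(self, i: int) -> RigidPose:
        return RigidPose(self.translations[i].copy(), self.quaternions[i].copy())

    @property
    def frames(self) -> list[TrajectoryFrame]:
        return [
            TrajectoryFrame(
                accepted_index=i,
                pose=self.pose(i),
                energy=EnergyComponents(float(self.vdw[i]), float(self.solvation[i])),
                min_surface_distance=float(self.min_surface_distance[i]),
            )
            for i in range(len(self))
        ]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accepted_index": np.arange(len(self)),
                "tx": self.translations[:, 0],
                "ty": self.translations[:, 1],
                "tz": self.translations[:, 2],
                "qx": self.quaternions[:, 0],
                "qy": self.quaternions[:, 1],
                "qz": self.quaternions[:, 2],
                "qw": self.quaternions[:, 3],
                "E_vdw": self.vdw,
                "E_solv": self.solvation,
                "E_total": self.total,
                "min_dist": self.min_surface_distance,
                "multiplicity": self.multiplicity,
            }
        )

    def save_tsv(self, path, header_comment: str = "") -> None:
        with Path(path).open("w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def load_tsv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            translations=df[["tx", "ty", "tz"]].to_numpy(),
            quaternions=df[["qx", "qy", "qz", "qw"]].to_numpy(),
            vdw=df["E_vdw"].to_numpy(),
            solvation=df["E_solv"].to_numpy(),
            min_surface_distance=df["min_dist"].to_numpy(),
            multiplicity=(
                df["multiplicity"].to_numpy() if "multiplicity" in df else None
            ),
        )

    def save_pdb_models(
        self, path, protein: MolecularStructure, stride: int = 100
    ) -> None:
        """Write every ``stride``-th accepted pose as a multi-model PDB."""
        centroid = protein.reference_centroid
        with Path(path).open("w") as fh:
            for model_no, i in enumerate(range(0, len(self), stride), start=1):
                fh.write(f"MODEL     {model_no:4d}\n")
                posed = self.pose(i).apply(protein.positions, centroid)
                _write_coords(fh, protein, posed)
                fh.write("ENDMDL\n")


def _write_coords(fh, structure: MolecularStructure, pos: np.ndarray) -> None:
    for i in range(structure.n_atoms):
        name = str(structure.name[i])
        name_field = f" {name:<3s}" if len(name) < 4 else name
        fh.write(
            f"ATOM  {int(structure.serial[i]) % 100000:5d} {name_field}"
            f" {str(structure.residue_name[i]):<4s}A"
            f"{int(structure.residue_index[i]) % 10000:4d}    "
            f"{pos[i, 0]:8.3f}{pos[i, 1]:8.3f}{pos[i, 2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          "
            f"{str(structure.element[i]):>2s}\n"
        )


def propose_move(pose: RigidPose, config: MCConfig, rng: np.random.Generator) -> RigidPose:
    """Symmetric rigid-body proposal (two-class mixture).

    With probability ``large_move_probability`` the step bounds are the
    ``large_*`` settings, otherwise the small-move settings.  Either way the
    increment is a uniform translation in ``[-s, s]^3`` plus a rotation about
    a uniform random axis by a uniform angle in ``[0, max]``, composed onto
    the current orientation.  The reverse increment has the same proposal
    density in both classes, so the mixture kernel is symmetric as plain
    Metropolis requires.
    """
    large = rng.random() < config.large_move_probability
    t_step = config.large_translation_step if large else config.max_translation_step
    r_step = config.large_rotation_step if large else config.max_rotation_step
    dt = rng.uniform(-t_step, t_step, size=3)
    axis = rng.standard_normal(3)
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
    angle = rng.uniform(0.0, np.deg2rad(r_step))
    drot = Rotation.from_rotvec(angle * axis)
    return pose.compose(dt, drot)


def metropolis_accept(
    delta_e: float, temperature: float, rng: np.random.Generator
) -> bool:
    """Accept with probability ``min(1, exp(-dE / kB T))``."""
    if math.isnan(delta_e):
        raise ValueError("NaN energy difference: broken energy evaluation")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    return rng.random() < math.exp(-delta_e / (KB * temperature))


def run_mc(
    protein: MolecularStructure,
    surface: SurfaceModel,
    config: MCConfig,
    initial_pose: RigidPose | None = None,
    energy_model: EnergyModel | None = None,
) -> Trajectory:
    """Run one Metropolis chain until ``target_accepted_moves`` acceptances.

    Rejected proposals are discarded without advancing the frame counter.
    Deterministic for fixed (structure, surface, config, seed).  Raises
    :class:`StallError` if ``stall_proposal_budget`` consecutive proposals
    are all rejected.
    """
    model = energy_model or EnergyModel(protein, surface, config.energy)
    rng = np.random.default_rng(config.seed)
    pose = initial_pose.copy() if initial_pose is not None else RigidPose.identity()
    energy, min_dist = model.evaluate(pose)
    if not math.isfinite(energy.total):
        raise ValueError("non-finite energy at the initial pose")
    n = config.target_accepted_moves
    translations = np.empty((n, 3))
    quaternions = np.empty((n, 4))
    vdw = np.empty(n)
    solv = np.empty(n)
    dists = np.empty(n)
    multiplicity = np.zeros(n, dtype=np.int64)
    accepted = 0
    proposals = 0
    since_last_accept = 0
    while accepted < n:
        candidate = propose_move(pose, config, rng)
        cand_energy, cand_dist = model.evaluate(candidate)
        proposals += 1
        if not math.isfinite(cand_energy.total):
            raise ValueError(f"non-finite energy at proposal {proposals}")
        if metropolis_accept(cand_energy.total - energy.total, config.temperature, rng):
            pose, energy, min_dist = candidate, cand_energy, cand_dist
            translations[accepted] = pose.translation
            quaternions[accepted] = pose.quaternion
            vdw[accepted] = energy.vdw
            solv[accepted] = energy.solvation
            dists[accepted] = min_dist
            multiplicity[accepted] = 1
            accepted += 1
            since_last_accept = 0
        else:
            if accepted > 0:
                multiplicity[accepted - 1] += 1
            since_last_accept += 1
            if since_last_accept >= config.stall_proposal_budget:
                raise StallError(
                    f"no acceptance in {since_last_accept} consecutive proposals "
                    f"({accepted}/{n} accepted so far)"
                )
    return Trajectory(translations, quaternions, vdw, solv, dists,
                      n_proposals=proposals, config=config,
                      multiplicity=multiplicity)


def detect_escape(
    trajectory: Trajectory, config: MCConfig
) -> tuple[bool, int | None]:
    """Flag a chain whose protein left the surface and did not return.

    True iff the trajectory ends with at least ``escape_patience`` consecutive
    accepted frames whose minimum surface distance exceeds
    ``escape_distance``; also returns the first frame of that terminal streak.
    Brief excursions followed by a return do not count.
    """
    d = trajectory.min_surface_distance
    if len(d) == 0:
        raise ValueError("empty trajectory")
    away = d > config.escape_distance
    if not away[-1]:
        return False, None
    # length of the terminal streak
    n = len(away)
    start = n
    while start > 0 and away[start - 1]:
        start -= 1
    if n - start >= config.escape_patience:
        return True, start
    return False, None


# --------------------------------------------------------------------------
# Starting poses
# --------------------------------------------------------------------------

def adsorbed_start_pose(
    protein: MolecularStructure,
    surface: SurfaceModel,
    height: float = 5.0,
    orientation: Rotation | None = None,
    rng: np.random.Generator | None = None,
) -> RigidPose:
    """Pose the protein just above the surface (minimum atom height ``height``).

    Orientation is the given rotation, or uniformly random when an ``rng`` is
    passed, or identity.
    """
    if orientation is None:
        orientation = Rotation.random(rng=rng) if rng is not None else Rotation.identity()
    pose = RigidPose(np.zeros(3), orientation.as_quat())
    posed = pose.apply(protein.positions, protein.reference_centroid)
    dz = (surface.plane_z + height) - posed[:, 2].min()
    centroid = protein.reference_centroid
    return RigidPose(np.array([-centroid[0], -centroid[1], dz]), orientation.as_quat())


def face_down_pose(
    protein: MolecularStructure,
    face_residue_names: list[str] | tuple[str, ...],
    surface: SurfaceModel,
    height: float = 5.0,
) -> RigidPose:
    """Lay the protein flat (long axis in-plane) with a chosen sidechain face
    pointing at the surface.

    Used to start amphipathic-helix chains with, e.g., the lysine face down.
    """
    axes = principal_axes(protein)
    xhat = np.array([1.0, 0.0, 0.0])
    rot1, _ = Rotation.align_vectors(xhat[None, :], axes.axis1[None, :])
    backbone = {"N", "CA", "C", "O", "OXT"}
    sel = np.array(
        [
            (str(rn).upper() in {r.upper() for r in face_residue_names})
            and (str(nm) not in backbone)
            for rn, nm in zip(protein.residue_name, protein.name)
        ]
    )
    if not sel.any():
        raise ValueError(f"no sidechain atoms for residues {face_residue_names}")
    centroid = protein.reference_centroid
    direction = rot1.apply(protein.positions[sel].mean(axis=0) - centroid)
    proj = np.array([0.0, direction[1], direction[2]])
    norm = np.linalg.norm(proj)
    if norm < 1e-9:
        raise ValueError("face direction is parallel to the helix axis")
    proj /= norm
    # rotate about x so that proj -> -z
    target = np.array([0.0, 0.0, -1.0])
    angle = np.arctan2(np.cross(proj, target)[0], proj @ target)
    rot2 = Rotation.from_rotvec(angle * xhat)
    orientation = rot2 * rot1
    pose = RigidPose(np.zeros(3), orientation.as_quat())
    posed = pose.apply(protein.positions, centroid)
    dz = (surface.plane_z + height) - posed[:, 2].min()
    return RigidPose(np.array([-centroid[0], -centroid[1], dz]), orientation.as_quat())
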