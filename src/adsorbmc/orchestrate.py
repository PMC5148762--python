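"""Multi-run orchestration: independent chains, escape filtering, basin
assignment and merged analyses.

Replicates the multi-chain protocol used to map adsorption orientations:
run N independent Metropolis chains from the same start, discard chains that
permanently leave the surface, pool the remaining frames into a free-energy
map, locate its minima, assign each chain to the basin its final frames
occupy, and merge contact profiles per basin.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import analysis
from .energy import EnergyModel
from .mc import MCConfig, Trajectory, detect_escape, run_mc
from .pose import RigidPose
from .structures import MolecularStructure
from .surface import SurfaceModel

__all__ = ["RunManifest", "OrchestrationResult", "orchestrate"]


@dataclasses.dataclass
class RunManifest:
    run_id: int
    seed: int
    status: str  # converged | escaped | stalled
    assigned_basin: int | None
    final_phi: float | None
    final_psi: float | None
    final_energy: float | None


@dataclasses.dataclass
class OrchestrationResult:
    manifests: list[RunManifest]
    trajectories: list[Trajectory]
    free_energy_map: analysis.FreeEnergyMap | None
    minima: list[tuple[int, int]]
    basin_profiles: dict[int, analysis.ContactProfile]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(m) for m in self.manifests])


def _modal_bin(orientations: np.ndarray, bin_width: float) -> tuple[int, int]:
    edges = np.arange(0.0, 180.0 + bin_width / 2, bin_width)
    counts, _, _ = np.histogram2d(orientations[:, 0], orientations[:, 1], bins=(edges, edges))
    return tuple(int(v) for v in np.unravel_index(np.argmax(counts), counts.shape))


def orchestrate(
    protein: MolecularStructure,
    surface: SurfaceModel,
    base_config: MCConfig,
    n_runs: int,
    seed_base: int = 0,
    initial_pose: RigidPose | None = None,
    bin_width: float = 10.0,
    contact_cutoff: float = 6.0,
) -> OrchestrationResult:
    """Run ``n_runs`` chains (seeds ``seed_base + i``) and merge analyses.

    Escaped chains are kept in the manifest but excluded from the pooled
    free-energy map, basin assignment and contact profiles.  A chain's basin
    is the minimum nearest (in bin space) to the modal orientation bin of its
    final 10% of frames.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    model = EnergyModel(protein, surface, base_config.energy)
    manifests: list[RunManifest] = []
    trajectories: list[Trajectory] = []
    orientations: list[np.ndarray] = []
    for i in range(n_runs):
        config = dataclasses.replace(base_config, seed=seed_base + i)
        try:
            traj = run_mc(protein, surface, config, initial_pose, energy_model=model)
            escaped, _ = detect_escape(traj, config)
            status = "escaped" if escaped else "converged"
        except RuntimeError:
            trajectories.append(Trajectory(
                np.empty((0, 3)), np.empty((0, 4)), np.empty(0), np.empty(0), np.empty(0)
            ))
            manifests.append(RunManifest(i, seed_base + i, "stalled", None, None, None, None))
            orientations.append(np.empty((0, 2)))
            continue
        trajectories.append(traj)
        ori = analysis.trajectory_orientations(traj, protein)
        orientations.append(ori)
        manifests.append(
            RunManifest(
                run_id=i,
                seed=seed_base + i,
                status=status,
                assigned_basin=None,
                final_phi=float(ori[-1, 0]),
                final_psi=float(ori[-1, 1]),
                final_energy=float(traj.total[-1]),
            )
        )
    converged = [i for i, m in enumerate(manifests) if m.status == "converged"]
    if not converged:
        raise RuntimeError("no adsorbed runs: every chain escaped or stalled")
    pooled = np.concatenate([orientations[i] for i in converged])
    fe_map = analysis.free_energy_map(pooled, base_config.temperature, bin_width)
    minima = analysis.find_minima(fe_map)
    if not minima:
        # single shallow basin: fall back to the global minimum bin
        minima = [
            tuple(int(v) for v in np.unravel_index(np.argmax(fe_map.counts), fe_map.counts.shape))
        ]
    basin_runs: dict[int, list[int]] = {b: [] for b in range(len(minima))}
    for i in converged:
        ori = orientations[i]
        tail = ori[int(np.floor(0.9 * len(ori))):]
        modal = _modal_bin(tail, bin_width)
        dists = [np.hypot(modal[0] - m[0], modal[1] - m[1]) for m in minima]
        basin = int(np.argmin(dists))
        manifests[i].assigned_basin = basin
        basin_runs[basin].append(i)
    basin_profiles = {}
    for basin, run_ids in basin_runs.items():
        profiles = []
        for i in run_ids:
            try:
                profiles.append(
                    analysis.contact_profile(trajectories[i], protein, surface, contact_cutoff)
                )
            except ValueError:
                continue
        if profiles:
            basin_profiles[basin] = analysis.merge_contact_profiles(profiles)
    return OrchestrationResult(
        manifests=manifests,
        trajectories=trajectories,
        free_energy_map=fe_map,
        minima=minima,
        basin_profiles=basin_profiles,
    )
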