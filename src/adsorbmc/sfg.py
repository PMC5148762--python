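"""Amide-I exciton model and vibrational SFG spectra (ssp / ppp).

One oscillator ("site") is placed on each backbone peptide bond, carrying a
transition dipole near the C=O bond (tilted toward the amide N), an axially
symmetric Raman tensor and a common site frequency.  Couplings between sites
use a Coulomb-like transition dipole coupling (TDC) form; a user-supplied
nearest-neighbor coupling function may replace TDC for adjacent amides.
Diagonalizing the resulting exciton Hamiltonian gives delocalized modes whose
IR dipoles and Raman tensors combine, as the outer product, into the
second-order response chi(2).  Spectra are reported as ``|chi_eff + B|^2``
with a fixed nonresonant background phase (defaults: 3.5 rad for ssp, 1.5 rad
for ppp), with chi averaged over the azimuth to model an in-plane isotropic
monolayer.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from .pose import RigidPose
from .structures import MolecularStructure

__all__ = [
    "AmideExcitonSystem",
    "SFGSpectrum",
    "build_amide_sites",
    "tdc_coupling",
    "build_hamiltonian",
    "compute_spectrum",
    "mix_spectra",
]

#: TDC prefactor, cm^-1 Å^3 per unit dipole^2
DEFAULT_TDC_PREFACTOR = 5034.0
#: unperturbed amide-I site frequency, cm^-1
DEFAULT_SITE_FREQUENCY = 1650.0
#: dipole tilt from the C=O bond toward N, degrees, in the O-C-N plane
DEFAULT_DIPOLE_TILT = 20.0
#: Raman tensor anisotropy (parallel : perpendicular)
DEFAULT_RAMAN_ANISOTROPY = 3.0
#: beam angles from the surface normal, degrees
VIS_ANGLE, IR_ANGLE = 47.0, 58.0
VIS_WAVENUMBER = 1.0e7 / 532.0  # 532 nm visible beam, cm^-1
#: default nonresonant background (amplitude 1) phases, rad
DEFAULT_BACKGROUND_PHASE = {"ssp": 3.5, "ppp": 1.5}


@dataclasses.dataclass
class AmideExcitonSystem:
    """Amide-I sites and their coupling Hamiltonian.

    ``hamiltonian`` has site frequencies on the diagonal and couplings
    (cm^-1) off-diagonal; it is symmetric by construction.
    """

    positions: np.ndarray  # (n, 3), Å
    dipoles: np.ndarray  # (n, 3), unit vectors * magnitude
    raman: np.ndarray  # (n, 3, 3)
    site_frequencies: np.ndarray  # (n,), cm^-1
    hamiltonian: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.site_frequencies)


@dataclasses.dataclass
class SFGSpectrum:
    frequencies: np.ndarray  # cm^-1
    chi2: np.ndarray  # complex effective chi(2) per frequency
    polarization: str
    background_phase: float
    background_amplitude: float = 1.0

    @property
    def background(self) -> complex:
        return self.background_amplitude * np.exp(1j * self.background_phase)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.chi2 + self.background) ** 2


def build_amide_sites(
    protein: MolecularStructure,
    pose: RigidPose | None = None,
    site_frequency: float = DEFAULT_SITE_FREQUENCY,
    dipole_tilt: float = DEFAULT_DIPOLE_TILT,
    raman_anisotropy: float = DEFAULT_RAMAN_ANISOTROPY,
) -> AmideExcitonSystem:
    """One amide-I site per peptide bond of a (posed) single-chain structure.

    The site sits at the midpoint of the C=O bond; its unit transition dipole
    is the C->O direction rotated by ``dipole_tilt`` degrees toward the amide
    N within the O-C-N plane.  The Raman tensor is axially symmetric about
    the dipole with the given parallel:perpendicular anisotropy.
    """
    pos = protein.positions
    if pose is not None:
        pos = pose.apply(pos, protein.reference_centroid)
    res_ids = np.unique(protein.residue_index)
    if len(res_ids) < 2:
        raise ValueError("need at least two residues to form a peptide bond")
    index = {}
    for i in range(protein.n_atoms):
        index[(int(protein.residue_index[i]), str(protein.name[i]))] = i
    positions, dipoles, tensors = [], [], []
    tilt = np.deg2rad(dipole_tilt)
    for r, r_next in zip(res_ids[:-1], res_ids[1:]):
        try:
            c = pos[index[(int(r), "C")]]
            o = pos[index[(int(r), "O")]]
            n = pos[index[(int(r_next), "N")]]
        except KeyError as exc:
            raise ValueError(
                f"missing backbone atom {exc.args[0][1]} in residue pair {r}-{r_next}"
            ) from None
        co = o - c
        co /= np.linalg.norm(co)
        cn = n - c
        cn -= (cn @ co) * co  # in-plane component orthogonal to C=O
        norm = np.linalg.norm(cn)
        if norm < 1e-9:
            raise ValueError(f"degenerate O-C-N plane at residue {r}")
        cn /= norm
        mu = np.cos(tilt) * co + np.sin(tilt) * cn
        positions.append(0.5 * (c + o))
        dipoles.append(mu)
        tensors.append(np.eye(3) + (raman_anisotropy - 1.0) * np.outer(mu, mu))
    n_sites = len(positions)
    return AmideExcitonSystem(
        positions=np.array(positions),
        dipoles=np.array(dipoles),
        raman=np.array(tensors),
        site_frequencies=np.full(n_sites, site_frequency),
    )


def tdc_coupling(
    pos_i: np.ndarray,
    pos_j: np.ndarray,
    mu_i: np.ndarray,
    mu_j: np.ndarray,
    prefactor: float = DEFAULT_TDC_PREFACTOR,
) -> float:
    """Transition dipole coupling, cm^-1.

    ``J = k [mu_i . mu_j - 3 (mu_i . r)(mu_j . r)] / r^3`` with unit vector r
    along the separation.  Side-by-side parallel dipoles couple positively;
    in-line parallel dipoles negatively with twice the magnitude.
    """
    r = np.asarray(pos_j, dtype=float) - np.asarray(pos_i, dtype=float)
    dist = np.linalg.norm(r)
    if dist == 0:
        raise ValueError("coincident amide sites")
    rhat = r / dist
    return float(
        prefactor
        * (np.dot(mu_i, mu_j) - 3.0 * np.dot(mu_i, rhat) * np.dot(mu_j, rhat))
        / dist**3
    )


def build_hamiltonian(
    system: AmideExcitonSystem,
    prefactor: float = DEFAULT_TDC_PREFACTOR,
    nearest_neighbor_coupling: Callable[[int, int], float] | None = None,
) -> np.ndarray:
    """Symmetric exciton Hamiltonian (cm^-1) from TDC couplings.

    ``nearest_neighbor_coupling(i, i+1)``, if given, replaces TDC for
    adjacent sites (the plug point for dihedral-map couplings).
    """
    n = system.n_sites
    h = np.diag(system.site_frequencies.astype(float))
    for i in range(n):
        for j in range(i + 1, n):
            if nearest_neighbor_coupling is not None and j == i + 1:
                coupling = float(nearest_neighbor_coupling(i, j))
            else:
                coupling = tdc_coupling(
                    system.positions[i], system.positions[j],
                    system.dipoles[i], system.dipoles[j], prefactor,
                )
            h[i, j] = h[j, i] = coupling
    system.hamiltonian = h
    return h


def _chi_components(system: AmideExcitonSystem, n_azimuth: int) -> dict:
    """Per-eigenmode lab-frame chi(2) tensor components, azimuthally averaged.

    Returns mode frequencies and the components needed for ssp/ppp:
    yyz, xzx (= per symmetry zxx here), zzz.
    """
    h = system.hamiltonian if system.hamiltonian is not None else build_hamiltonian(system)
    if not np.allclose(h, h.T):
        raise ValueError("Hamiltonian must be symmetric")
    evals, evecs = np.linalg.eigh(h)
    n = system.n_sites
    angles = 2.0 * np.pi * np.arange(n_azimuth) / n_azimuth
    comp = {"yyz": np.zeros(n), "xzx": np.zeros(n), "zxx": np.zeros(n), "zzz": np.zeros(n)}
    for ang in angles:
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        mu_rot = system.dipoles @ rot.T
        raman_rot = np.einsum("ab,nbc,dc->nad", rot, system.raman, rot)
        for k in range(n):
            v = evecs[:, k]
            mu_k = v @ mu_rot
            a_k = np.einsum("n,nab->ab", v, raman_rot)
            comp["yyz"][k] += a_k[1, 1] * mu_k[2]
            comp["xzx"][k] += a_k[0, 2] * mu_k[0]
            comp["zxx"][k] += a_k[2, 0] * mu_k[0]
            comp["zzz"][k] += a_k[2, 2] * mu_k[2]
    for key in comp:
        comp[key] /= n_azimuth
    return {"frequencies": evals, **comp}


def compute_spectrum(
    system: AmideExcitonSystem,
    polarization: str = "ssp",
    background_phase: float | None = None,
    background_amplitude: float = 1.0,
    linewidth: float = 10.0,
    grid: np.ndarray | None = None,
    n_azimuth: int = 36,
) -> SFGSpectrum:
    """SFG spectrum of an exciton system for one polarization combination.

    Each eigenmode contributes a complex Lorentzian of the given homogeneous
    ``linewidth`` (cm^-1) weighted by its effective chi(2) amplitude; the
    effective amplitude combines the azimuthally averaged tensor components
    with the beam geometry (visible/IR input angles 47 and 58 degrees, unit
    Fresnel factors).  Intensity is ``|chi_eff + B e^{i phase}|^2``.
    """
    if polarization not in ("ssp", "ppp"):
        raise ValueError("polarization must be 'ssp' or 'ppp'")
    if linewidth <= 0:
        raise ValueError("linewidth must be positive")
    if system.n_sites == 0:
        raise ValueError("empty exciton system")
    if background_phase is None:
        background_phase = DEFAULT_BACKGROUND_PHASE[polarization]
    if grid is None:
        center = float(np.mean(system.site_frequencies))
        grid = np.arange(center - 100.0, center + 100.0 + 0.5, 1.0)
    comp = _chi_components(system, n_azimuth)
    freqs = comp["frequencies"]
    theta_vis = np.deg2rad(VIS_ANGLE)
    theta_ir = np.deg2rad(IR_ANGLE)
    ir_center = float(np.mean(system.site_frequencies))
    sfg_wavenumber = VIS_WAVENUMBER + ir_center
    sin_sfg = (
        VIS_WAVENUMBER * np.sin(theta_vis) + ir_center * np.sin(theta_ir)
    ) / sfg_wavenumber
    theta_sfg = np.arcsin(np.clip(sin_sfg, -1.0, 1.0))
    if polarization == "ssp":
        amplitudes = np.sin(theta_ir) * comp["yyz"]
    else:
        amplitudes = (
            -np.cos(theta_sfg) * np.cos(theta_vis) * np.sin(theta_ir) * comp["yyz"]
            - np.cos(theta_sfg) * np.sin(theta_vis) * np.cos(theta_ir) * comp["xzx"]
            + np.sin(theta_sfg) * np.cos(theta_vis) * np.cos(theta_ir) * comp["zxx"]
            + np.sin(theta_sfg) * np.sin(theta_vis) * np.sin(theta_ir) * comp["zzz"]
        )
    chi = np.zeros(len(grid), dtype=complex)
    for k in range(len(freqs)):
        chi += amplitudes[k] / (freqs[k] - grid - 1j * linewidth)
    return SFGSpectrum(
        frequencies=np.asarray(grid, dtype=float),
        chi2=chi,
        polarization=polarization,
        background_phase=float(background_phase),
        background_amplitude=float(background_amplitude),
    )


def mix_spectra(spectra: list[SFGSpectrum], weights) -> SFGSpectrum:
    """Coherent mixture of orientations in one monolayer.

    The complex chi(2) responses are weight-averaged *before* squaring, so
    intensities are non-additive (interference between orientations); the
    nonresonant background is applied once to the mixture.
    """
    weights = np.asarray(weights, dtype=float)
    if len(spectra) == 0 or len(weights) != len(spectra):
        raise ValueError("need one weight per spectrum")
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    base = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.frequencies, base.frequencies):
            raise ValueError("frequency grid mismatch")
        if s.polarization != base.polarization:
            raise ValueError("polarization mismatch")
    chi = sum(w * s.chi2 for w, s in zip(weights, spectra))
    return SFGSpectrum(
        frequencies=base.frequencies.copy(),
        chi2=chi,
        polarization=base.polarization,
        background_phase=base.background_phase,
        background_amplitude=base.background_amplitude,
    )
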