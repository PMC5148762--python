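import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from adsorbmc import RigidPose, build_alpha_helix
from adsorbmc.sfg import (
    DEFAULT_BACKGROUND_PHASE,
    build_amide_sites,
    build_hamiltonian,
    compute_spectrum,
    mix_spectra,
    tdc_coupling,
)


@pytest.fixture(scope="module")
def helix5():
    return build_alpha_helix("AAAAA")


class TestBuildAmideSites:
    def test_one_site_per_peptide_bond(self, helix5):
        system = build_amide_sites(helix5)
        assert system.n_sites == 4  # 5 residues -> 4 peptide bonds
        two_res = helix5.select(helix5.residue_index <= 2)
        assert build_amide_sites(two_res).n_sites == 1

    def test_dipoles_translation_invariant_rotation_equivariant(self, helix5):
        base = build_amide_sites(helix5)
        shifted = build_amide_sites(
            helix5, RigidPose(np.array([3.0, -2.0, 7.0]), [0, 0, 0, 1])
        )
        assert np.allclose(base.dipoles, shifted.dipoles, atol=1e-12)
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True)
        rotated = build_amide_sites(helix5, RigidPose(np.zeros(3), rot.as_quat()))
        assert np.allclose(rot.apply(base.dipoles), rotated.dipoles, atol=1e-9)

    def test_missing_backbone_atom_is_an_error(self, helix5):
        broken = helix5.select(helix5.name != "O")
        with pytest.raises(ValueError, match="missing backbone atom"):
            build_amide_sites(broken)

    def test_unit_dipoles_near_carbonyl(self, helix5):
        system = build_amide_sites(helix5)
        assert np.allclose(np.linalg.norm(system.dipoles, axis=1), 1.0, atol=1e-12)
        # site positions sit on the C=O bond midpoints
        c = helix5.positions[(helix5.name == "C")][:-1]
        o = helix5.positions[(helix5.name == "O")][:-1]
        assert np.allclose(system.positions, 0.5 * (c + o), atol=1e-12)


class TestTdcCoupling:
    def test_side_by_side_vs_in_line_factor(self):
        mu = np.array([0.0, 0.0, 1.0])
        side = tdc_coupling([0, 0, 0], [4.0, 0, 0], mu, mu)
        line = tdc_coupling([0, 0, 0], [0, 0, 4.0], mu, mu)
        assert side > 0 > line
        assert line == pytest.approx(-2.0 * side, rel=1e-12)

    def test_inverse_cube_scaling(self):
        mu = np.array([0.0, 0.0, 1.0])
        near = tdc_coupling([0, 0, 0], [3.0, 0, 0], mu, mu)
        far = tdc_coupling([0, 0, 0], [6.0, 0, 0], mu, mu)
        assert far == pytest.approx(near / 8.0, rel=1e-12)

    def test_orthogonal_dipoles_decouple(self):
        a = np.array([0.0, 0.0, 1.0])
        b = np.array([0.0, 1.0, 0.0])
        assert tdc_coupling([0, 0, 0], [4.0, 0, 0], a, b) == pytest.approx(0.0, abs=1e-15)

    def test_coincident_sites_rejected(self):
        mu = np.array([0.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            tdc_coupling([1, 1, 1], [1, 1, 1], mu, mu)


class TestComputeSpectrum:
    def test_hamiltonian_symmetric_with_site_frequencies_on_diagonal(self, helix5):
        system = build_amide_sites(helix5)
        h = build_hamiltonian(system)
        assert np.array_equal(h, h.T)
        assert np.allclose(np.diag(h), system.site_frequencies)

    def test_trace_conservation(self, helix5):
        system = build_amide_sites(helix5)
        h = build_hamiltonian(system)
        evals = np.linalg.eigvalsh(h)
        assert evals.sum() == pytest.approx(system.site_frequencies.sum(), rel=1e-12)

    def test_single_site_lorentzian_peaks_at_site_frequency(self, helix5):
        one = build_amide_sites(helix5.select(helix5.residue_index <= 2))
        build_hamiltonian(one)
        spec = compute_spectrum(one, "ssp", background_amplitude=0.0,
                                grid=np.arange(1550.0, 1751.0, 0.5))
        peak = spec.frequencies[np.argmax(spec.intensity)]
        assert peak == pytest.approx(1650.0, abs=1.0)

    def test_two_site_exciton_splitting_closed_form(self):
        """Two parallel coupled sites: eigenfrequencies nu0 ± J, and the
        out-of-phase (dark) combination carries no intensity."""
        from adsorbmc.sfg import AmideExcitonSystem

        mu = np.array([0.0, 0.0, 1.0])
        raman = np.eye(3) + 2.0 * np.outer(mu, mu)
        system = AmideExcitonSystem(
            positions=np.array([[0.0, 0, 1.0], [4.0, 0, 1.0]]),
            dipoles=np.array([mu, mu]),
            raman=np.array([raman, raman]),
            site_frequencies=np.array([1650.0, 1650.0]),
        )
        h = build_hamiltonian(system)
        j = h[0, 1]
        assert j > 0
        evals = np.linalg.eigvalsh(h)
        assert np.allclose(sorted(evals), sorted([1650.0 - j, 1650.0 + j]), atol=1e-9)
        spec = compute_spectrum(system, "ssp", background_amplitude=0.0,
                                grid=np.arange(1550.0, 1801.0, 0.25), linewidth=1.0)
        peak = spec.frequencies[np.argmax(spec.intensity)]
        # bright symmetric mode at nu0 + J; dark mode invisible
        assert peak == pytest.approx(1650.0 + j, abs=0.5)
        dark_idx = np.argmin(np.abs(spec.frequencies - (1650.0 - j)))
        assert spec.intensity[dark_idx] < 0.01 * spec.intensity.max()

    def test_default_background_phases(self, helix5):
        system = build_amide_sites(helix5)
        build_hamiltonian(system)
        assert compute_spectrum(system, "ssp").background_phase == 3.5
        assert compute_spectrum(system, "ppp").background_phase == 1.5
        assert DEFAULT_BACKGROUND_PHASE == {"ssp": 3.5, "ppp": 1.5}

    def test_intensity_nonnegative_and_background_floor(self, helix5):
        system = build_amide_sites(helix5)
        build_hamiltonian(system)
        spec = compute_spectrum(system, "ppp")
        assert (spec.intensity >= 0).all()
        far_grid = np.array([800.0, 5000.0])
        far = compute_spectrum(system, "ppp", grid=far_grid)
        assert np.allclose(far.intensity, abs(far.background) ** 2, rtol=1e-2)

    def test_azimuthal_placement_invariance(self, helix5):
        """The 36-point azimuthal average makes the monolayer response exactly
        independent of how the molecule is turned about the surface normal."""
        grid = np.arange(1600.0, 1701.0, 1.0)
        base_sys = build_amide_sites(helix5)
        build_hamiltonian(base_sys)
        base = compute_spectrum(base_sys, "ppp", grid=grid)
        rot = Rotation.from_euler("z", 37.3, degrees=True)
        turned_sys = build_amide_sites(helix5, RigidPose(np.zeros(3), rot.as_quat()))
        build_hamiltonian(turned_sys)
        turned = compute_spectrum(turned_sys, "ppp", grid=grid)
        assert np.allclose(base.intensity, turned.intensity, rtol=1e-9, atol=1e-12)


class TestMixSpectra:
    def _spectrum(self, chi, phase=3.5):
        from adsorbmc.sfg import SFGSpectrum

        grid = np.arange(1600.0, 1701.0, 1.0)
        return SFGSpectrum(grid, np.full(len(grid), chi, dtype=complex), "ssp", phase)

    def test_weight_one_is_identity(self):
        a = self._spectrum(1.0 + 0.5j)
        b = self._spectrum(-2.0 + 0.1j)
        mixed = mix_spectra([a, b], [1.0, 0.0])
        assert np.array_equal(mixed.chi2, a.chi2)

    def test_opposite_phases_cancel_coherently(self):
        a = self._spectrum(1.0 + 0.5j, phase=0.0)
        b = self._spectrum(-1.0 - 0.5j, phase=0.0)
        mixed = mix_spectra([a, b], [0.5, 0.5])
        mixed.background_amplitude = 0.0
        assert np.allclose(mixed.intensity, 0.0, atol=1e-24)

    def test_idempotent_on_identical_inputs(self):
        a = self._spectrum(0.7 - 0.2j)
        mixed = mix_spectra([a, a], [0.5, 0.5])
        assert np.allclose(mixed.chi2, a.chi2)
        assert np.allclose(mixed.intensity, a.intensity)

    def test_mixture_differs_from_both_components(self, helix5):
        """Coherent averaging of two different orientations yields a spectrum
        that is not the intensity average and differs from both inputs."""
        grid = np.arange(1600.0, 1701.0, 1.0)
        sys_a = build_amide_sites(helix5)
        build_hamiltonian(sys_a)
        spec_a = compute_spectrum(sys_a, "ssp", grid=grid)
        flip = Rotation.from_euler("x", 180, degrees=True)
        sys_b = build_amide_sites(helix5, RigidPose(np.zeros(3), flip.as_quat()))
        build_hamiltonian(sys_b)
        spec_b = compute_spectrum(sys_b, "ssp", grid=grid)
        mixed = mix_spectra([spec_a, spec_b], [0.5, 0.5])
        assert not np.allclose(mixed.intensity, spec_a.intensity, rtol=1e-3)
        assert not np.allclose(mixed.intensity, spec_b.intensity, rtol=1e-3)
        naive = 0.5 * spec_a.intensity + 0.5 * spec_b.intensity
        assert not np.allclose(mixed.intensity, naive, rtol=1e-3)

    def test_grid_and_weight_validation(self):
        a = self._spectrum(1.0)
        b = self._spectrum(1.0)
        b.frequencies = b.frequencies + 5.0
        with pytest.raises(ValueError, match="grid"):
            mix_spectra([a, b], [0.5, 0.5])
        with pytest.raises(ValueError, match="sum"):
            mix_spectra([a, self._spectrum(1.0)], [0.6, 0.6])
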