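import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from adsorbmc import (
    assign_groups,
    build_alpha_helix,
    principal_axes,
    read_pdb,
)
from adsorbmc.parameters import Group, UnknownResidueError, classify_atom
from adsorbmc.structures import DegenerateInertiaError, PDBParseError

from .conftest import LK_SEQUENCE, toy_structure


class TestReadPdb:
    def test_single_alanine_atom_and_residue_counts(self, ala_pdb):
        full = read_pdb(ala_pdb, keep_hydrogens=True)
        assert full.n_atoms == 10
        assert full.n_residues == 1
        heavy = read_pdb(ala_pdb)
        assert heavy.n_atoms == 5
        assert set(heavy.name) == {"N", "CA", "C", "O", "CB"}

    def test_empty_file_reports_no_atom_records(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER  nothing here\nEND\n")
        with pytest.raises(PDBParseError, match="no ATOM records"):
            read_pdb(path)

    def test_malformed_coordinates_name_the_line(self, tmp_path, ala_pdb):
        text = ala_pdb.read_text().splitlines()
        text[2] = text[2][:30] + "  badnum" + text[2][38:]
        bad = tmp_path / "bad.pdb"
        bad.write_text("\n".join(text) + "\n")
        with pytest.raises(PDBParseError, match=r"bad\.pdb:3"):
            read_pdb(bad)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_pdb(tmp_path / "absent.pdb")

    def test_unknown_residues_flagged_not_dropped(self, tmp_path, ala_pdb):
        text = ala_pdb.read_text().replace("ALA ", "XYZ ")
        path = tmp_path / "odd.pdb"
        path.write_text(text)
        structure = read_pdb(path)
        assert structure.n_atoms == 5
        assert structure.unknown_residues == ("XYZ",)


class TestAssignGroups:
    @pytest.mark.parametrize(
        "residue, atom, expected",
        [
            ("LEU", "CD1", Group.HYDROPHOBIC_SIDECHAIN),
            ("SER", "OG", Group.HYDROPHILIC_SIDECHAIN),
            ("TYR", "OH", Group.HYDROPHILIC_SIDECHAIN),
            ("TYR", "CZ", Group.HYDROPHOBIC_SIDECHAIN),
            ("LYS", "NZ", Group.HYDROPHILIC_SIDECHAIN),
            ("ALA", "CA", Group.HYDROPHOBIC_BACKBONE),
            ("LYS", "C", Group.HYDROPHOBIC_BACKBONE),
            ("LEU", "O", Group.HYDROPHILIC_BACKBONE),
            ("LEU", "N", Group.HYDROPHILIC_BACKBONE),
            ("GRA", "C", Group.SURFACE_CARBON),
        ],
    )
    def test_classification_examples(self, residue, atom, expected):
        assert classify_atom(residue, atom, atom[0]) == expected

    def test_unknown_residue_is_an_error(self):
        with pytest.raises(UnknownResidueError, match="XYZ"):
            classify_atom("XYZ", "CA2", "C")

    def test_ambiguous_tyr_atom_is_an_error(self):
        with pytest.raises(UnknownResidueError, match="Tyr"):
            classify_atom("TYR", "QQ", "C")

    def test_assignment_total_and_parameters_set(self, lk_helix):
        assert (lk_helix.group >= 0).all()
        protein_groups = set(int(g) for g in lk_helix.group)
        assert protein_groups <= {
            int(Group.HYDROPHOBIC_SIDECHAIN),
            int(Group.HYDROPHILIC_SIDECHAIN),
            int(Group.HYDROPHOBIC_BACKBONE),
            int(Group.HYDROPHILIC_BACKBONE),
        }
        assert np.isfinite(lk_helix.lj_epsilon).all()
        assert (lk_helix.lj_epsilon >= 0).all()
        assert (lk_helix.sasa_radius > 0).all()

    def test_glycine_contributes_backbone_only(self):
        helix = assign_groups(build_alpha_helix("GGGG"))
        assert int(Group.HYDROPHOBIC_SIDECHAIN) not in set(int(g) for g in helix.group)

    def test_parameter_override_file(self, tmp_path):
        from adsorbmc.parameters import load_parameter_overrides

        path = tmp_path / "params.tsv"
        path.write_text(
            "residue\tatom\tepsilon_kJmol\trmin_half_A\tradius_A\tgroup\n"
            "LEU\tCD1\t0.5\t2.5\t1.9\thydrophilic_sidechain\n"
            "*\tCA\t\t\t1.8\t\n"
        )
        overrides = load_parameter_overrides(path)
        helix = assign_groups(build_alpha_helix("LKLL"), overrides)
        cd1 = (helix.residue_name == "LEU") & (helix.name == "CD1")
        assert np.allclose(helix.lj_epsilon[cd1], 0.5)
        assert np.allclose(helix.lj_rmin_half[cd1], 2.5)
        assert np.allclose(helix.sasa_radius[cd1], 1.9)
        assert set(helix.group[cd1]) == {int(Group.HYDROPHILIC_SIDECHAIN)}
        assert np.allclose(helix.sasa_radius[helix.name == "CA"], 1.8)


class TestBuildAlphaHelix:
    def test_lk_helix_is_amphipathic(self, lk_helix):
        backbone = {"N", "CA", "C", "O"}
        centroid = lk_helix.reference_centroid
        sel = {}
        for resn in ("LEU", "LYS"):
            mask = np.array(
                [rn == resn and nm not in backbone
                 for rn, nm in zip(lk_helix.residue_name, lk_helix.name)]
            )
            d = lk_helix.positions[mask].mean(axis=0) - centroid
            d[2] = 0.0  # project off the helix axis (z by construction)
            sel[resn] = d / np.linalg.norm(d)
        angle = np.degrees(np.arccos(np.clip(sel["LEU"] @ sel["LYS"], -1, 1)))
        assert angle > 120.0
        assert lk_helix.n_residues == 14

    def test_polyalanine_rise_per_residue(self):
        helix = build_alpha_helix("AAAAAAAA")
        ca = helix.positions[helix.name == "CA"]
        rise = (ca[-1, 2] - ca[0, 2]) / (len(ca) - 1)
        assert rise == pytest.approx(1.5, abs=0.1)

    @pytest.mark.parametrize("sequence", ["AX", "AAXA", "AA"])
    def test_invalid_or_short_sequences_rejected(self, sequence):
        with pytest.raises(ValueError):
            build_alpha_helix(sequence)

    def test_bit_reproducible(self):
        a = build_alpha_helix(LK_SEQUENCE)
        b = build_alpha_helix(LK_SEQUENCE)
        assert np.array_equal(a.positions, b.positions)


class TestPrincipalAxes:
    def test_box_corner_axes_follow_extents(self):
        corners = np.array(
            [[x, y, z] for x in (0, 4.0) for y in (0, 2.0) for z in (0, 1.0)]
        )
        axes = principal_axes(toy_structure(corners))
        assert abs(axes.axis1 @ [1, 0, 0]) == pytest.approx(1.0, abs=1e-12)
        assert abs(axes.axis2 @ [0, 1, 0]) == pytest.approx(1.0, abs=1e-12)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(7)
        pos = rng.normal(size=(40, 3)) * [5.0, 2.0, 1.0]
        base = principal_axes(toy_structure(pos))
        for seed in range(3):
            rot = Rotation.random(rng=np.random.default_rng(seed))
            rotated = principal_axes(toy_structure(rot.apply(pos)))
            for a, b in zip(base.matrix, rotated.matrix):
                assert np.allclose(rot.apply(a), b, atol=1e-8)
            assert np.allclose(base.eigenvalues, rotated.eigenvalues, atol=1e-8)

    def test_collinear_atoms_raise(self):
        pos = np.zeros((10, 3))
        pos[:, 2] = np.arange(10)
        with pytest.raises(DegenerateInertiaError):
            principal_axes(toy_structure(pos))

    def test_helix_axis_matches_ca_line_fit(self, lk_helix):
        axes = principal_axes(lk_helix)
        ca = lk_helix.positions[lk_helix.name == "CA"]
        _, _, vt = np.linalg.svd(ca - ca.mean(axis=0))
        fit = vt[0]
        angle = np.degrees(np.arccos(np.clip(abs(axes.axis1 @ fit), -1, 1)))
        assert angle < 5.0
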