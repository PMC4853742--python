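import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ticseq.structures import (
    STANDARD_RESIDUES,
    AminoAcidStructure,
    Conformation,
    GeometryError,
    UnknownResidueError,
    apply_conformation,
    load_residue_template,
    mean_surface_radius,
    plane_exclusion_area,
    shell_volume,
)

from _oracles import mc_plane_free_area, mc_shell_volume, ray_march_mean_radius


class TestTemplates:
    def test_all_twenty_load_centered(self):
        for code in STANDARD_RESIDUES:
            s = load_residue_template(code)
            assert s.n_atoms > 0
            assert np.all(s.vdw_radii > 0)
            bb = s.coords[sorted(s.backbone_atom_indices)]
            # backbone centroid sits on the channel axis
            assert np.allclose(bb.mean(axis=0)[:2], 0.0, atol=5e-3)
            assert s.terminal_z_extent > 0

    def test_glycine_is_smallest(self):
        counts = {c: load_residue_template(c).n_atoms for c in STANDARD_RESIDUES}
        assert min(counts, key=counts.get) == "GLY"
        assert counts["TRP"] > counts["GLY"]

    def test_unknown_residue_raises(self):
        with pytest.raises(UnknownResidueError):
            load_residue_template("XXX")

    def test_proline_phi_locked(self):
        pro = load_residue_template("PRO")
        assert pro.phi_moving == ()
        assert len(pro.psi_moving) > 0


class TestConformation:
    def test_angles_wrap_into_range(self):
        c = Conformation(phi=270.0, psi=-540.0, azimuth=360.0)
        assert c.phi == -90.0
        assert c.psi == 180.0
        assert c.azimuth == 0.0

    def test_identity_conformation_is_noop(self, lys):
        posed = apply_conformation(lys, Conformation(180.0, 180.0, 0.0))
        assert np.allclose(posed.coords, lys.coords, atol=1e-12)

    def test_full_turn_azimuth_is_noop(self, lys):
        posed = apply_conformation(lys, Conformation(azimuth=360.0))
        assert np.allclose(posed.coords, lys.coords, atol=1e-9)

    def test_azimuth_rotations_compose(self, lys):
        twice = apply_conformation(
            apply_conformation(lys, Conformation(azimuth=90.0)),
            Conformation(azimuth=90.0),
        )
        once = apply_conformation(lys, Conformation(azimuth=180.0))
        assert np.allclose(twice.coords, once.coords, atol=1e-9)

    def test_dihedral_rotation_is_rigid(self, lys):
        """Bond lengths and intra-partition distances survive posing."""
        posed = apply_conformation(lys, Conformation(phi=-150.0, psi=140.0, azimuth=33.0))

        def pairwise(coords, idx):
            sub = coords[list(idx)]
            return np.linalg.norm(sub[:, None] - sub[None, :], axis=-1)

        core = tuple(
            set(range(lys.n_atoms)) - set(lys.phi_moving) - set(lys.psi_moving)
        )
        for group in (lys.phi_moving, lys.psi_moving, core):
            assert np.allclose(
                pairwise(posed.coords, group), pairwise(lys.coords, group), atol=1e-9
            )

    def test_pivot_atoms_stay_put_under_dihedrals(self, lys):
        posed = apply_conformation(lys, Conformation(phi=-120.0, psi=120.0))
        names = lys.atom_names
        for name in ("N", "CA", "C"):
            i = names.index(name)
            assert np.allclose(posed.coords[i], lys.coords[i], atol=1e-12)


class TestMeanSurfaceRadius:
    def test_single_sphere(self):
        s = AminoAcidStructure.from_spheres([[0, 0, 0]], [1.7])
        assert mean_surface_radius(s, 10_000) == pytest.approx(1.7, abs=1e-9)

    def test_two_sphere_union_matches_ray_marching(self, two_spheres):
        expected = ray_march_mean_radius(
            two_spheres.coords, two_spheres.vdw_radii, n_rays=200_000, seed=3
        )
        got = mean_surface_radius(two_spheres, 200_000)
        assert got == pytest.approx(expected, rel=2e-3)

    def test_bounded_by_farthest_sphere(self, lys):
        bound = np.max(np.linalg.norm(lys.coords, axis=1) + lys.vdw_radii)
        assert mean_surface_radius(lys, 50_000) <= bound

    def test_azimuthal_invariance(self, lys):
        rotated = apply_conformation(lys, Conformation(azimuth=73.0))
        a = mean_surface_radius(lys, 200_000)
        b = mean_surface_radius(rotated, 200_000)
        assert a == pytest.approx(b, rel=1e-3)

    def test_origin_outside_raises(self):
        s = AminoAcidStructure.from_spheres([[5.0, 0, 0]], [1.0])
        with pytest.raises(GeometryError):
            mean_surface_radius(s, 100)


class TestShellVolume:
    def test_analytic_spherical_shell(self):
        s = AminoAcidStructure.from_spheres([[0, 0, 0]], [2.0])
        expect = 4.0 / 3.0 * np.pi * (2.5**3 - 2.0**3)
        assert shell_volume(s, 0.0, 0.5, 0.05) == pytest.approx(expect, rel=0.02)

    def test_empty_shell_is_zero(self, single_sphere):
        assert shell_volume(single_sphere, 1.0, 1.0) == 0.0

    def test_overlapping_spheres_match_monte_carlo(self, two_spheres):
        expect = mc_shell_volume(
            two_spheres.coords, two_spheres.vdw_radii, 0.5, 1.5,
            n_points=10_000_000, seed=9,
        )
        got = shell_volume(two_spheres, 0.5, 1.5, 0.05)
        assert got == pytest.approx(expect, rel=0.02)

    def test_contiguous_shells_are_additive(self, two_spheres):
        v01 = shell_volume(two_spheres, 0.0, 1.0, 0.1)
        v12 = shell_volume(two_spheres, 1.0, 2.0, 0.1)
        v02 = shell_volume(two_spheres, 0.0, 2.0, 0.1)
        assert v01 + v12 == pytest.approx(v02, rel=1e-12)

    def test_grid_refinement_converges(self, single_sphere):
        exact = 4.0 / 3.0 * np.pi * (2.5**3 - 2.0**3)
        errs = [
            abs(shell_volume(single_sphere, 0.0, 0.5, h) - exact)
            for h in (0.4, 0.2, 0.1)
        ]
        assert errs[2] < errs[0]

    def test_invalid_bounds_raise(self, single_sphere):
        with pytest.raises(ValueError):
            shell_volume(single_sphere, 0.0, np.inf)
        with pytest.raises(ValueError):
            shell_volume(single_sphere, -1.0, 0.5)


class TestPlaneExclusionArea:
    def test_empty_disk(self):
        s = AminoAcidStructure.from_spheres(np.empty((0, 3)), [])
        got = plane_exclusion_area(s, 0.0, 17.5, z_margin=None)
        assert got == pytest.approx(np.pi * 17.5**2, rel=0.005)

    def test_single_slice_annulus(self):
        s = AminoAcidStructure.from_spheres([[0, 0, 0]], [1.7])
        got = plane_exclusion_area(s, 1.3, 17.5, z_margin=None)
        assert got == pytest.approx(np.pi * (17.5**2 - 3.0**2), rel=0.005)

    def test_lys_against_rejection_sampling(self, lys):
        z_window = lys.terminal_z_extent + 1.9
        expect = mc_plane_free_area(
            lys.coords, lys.vdw_radii, 5.38, 17.5, z_window,
            n_points=10_000_000, seed=4,
        )
        got = plane_exclusion_area(lys, 5.38, 17.5, z_margin=1.9)
        assert got == pytest.approx(expect, rel=0.01)

    def test_full_coverage_returns_zero(self, single_sphere):
        assert plane_exclusion_area(single_sphere, 40.0, 5.0, z_margin=None) == 0.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        inflate_lo=st.floats(0.0, 4.0),
        delta=st.floats(0.1, 4.0),
        seed=st.integers(0, 100),
    )
    def test_monotone_in_inflation(self, inflate_lo, delta, seed):
        r = np.random.default_rng(seed)
        s = AminoAcidStructure.from_spheres(
            r.normal(0, 2, (5, 3)), r.uniform(1.0, 2.0, 5)
        )
        a_lo = plane_exclusion_area(s, inflate_lo, 12.0, z_margin=None, grid_step=0.1)
        a_hi = plane_exclusion_area(s, inflate_lo + delta, 12.0, z_margin=None, grid_step=0.1)
        assert a_hi <= a_lo

    def test_grid_refinement_converges(self):
        s = AminoAcidStructure.from_spheres([[0, 0, 0]], [1.7])
        exact = np.pi * (17.5**2 - 3.0**2)
        errs = [
            abs(plane_exclusion_area(s, 1.3, 17.5, z_margin=None, grid_step=h) - exact)
            for h in (0.4, 0.2, 0.1)
        ]
        assert errs[2] < errs[0]
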