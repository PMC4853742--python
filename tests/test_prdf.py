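import io

import numpy as np
import pytest

from ticseq.constants import MOLAR_TO_PER_A3
from ticseq.pipeline import fixture_prdfs, load_fixture_params
from ticseq.prdf import (
    PRDF,
    ProfileParams,
    bulk_onset,
    compute_prdf,
    default_shell_midpoints,
    read_ion_frames,
    synthesize_prdf,
)
from ticseq.structures import AminoAcidStructure, shell_volume

from _oracles import mc_shell_volume


class TestComputePRDF:
    def test_empty_frames_give_zero_concentration(self, single_sphere):
        frames = [np.empty((0, 3))] * 3
        p = compute_prdf(frames, single_sphere, "K+", r_max=4.0)
        assert np.all(p.g == 0.0)

    def test_no_frames_raises(self, single_sphere):
        with pytest.raises(ValueError):
            compute_prdf([], single_sphere, "K+")

    def test_single_ion_in_first_shell(self, single_sphere):
        """One ion 0.25 A off the surface: g = 1/V(first shell), rest zero."""
        frames = [np.array([[2.25, 0.0, 0.0]])]
        p = compute_prdf(frames, single_sphere, "K+", r_max=4.0, grid_step=0.05)
        v_oracle = mc_shell_volume([[0, 0, 0]], [2.0], 0.0, 0.5,
                                   n_points=2_000_000, seed=2)
        expected = 1.0 / v_oracle / MOLAR_TO_PER_A3
        assert p.g[0] == pytest.approx(expected, rel=0.02)
        assert np.all(p.g[1:] == 0.0)

    def test_uniform_bulk_recovered(self, single_sphere):
        """Ions at bulk density give every shell ~g_bulk (Poisson 3 sigma)."""
        rng = np.random.default_rng(7)
        half = 7.0
        density = MOLAR_TO_PER_A3  # 1 mol/L in ions per A^3
        lam = density * (2 * half) ** 3
        n_frames = 8000
        counts = rng.poisson(lam, n_frames)
        frames = [rng.uniform(-half, half, (c, 3)) for c in counts]
        p = compute_prdf(frames, single_sphere, "K+", r_max=4.0, grid_step=0.1)
        for k in range(len(p.r_mid)):
            vol = shell_volume(single_sphere, k * 0.5, (k + 1) * 0.5, 0.1)
            total_expected = density * vol * n_frames
            se = np.sqrt(total_expected) / total_expected
            assert abs(p.g[k] - 1.0) < 3 * se + 0.02

    def test_linear_in_frame_counts(self, single_sphere):
        f1 = [np.array([[2.25, 0.0, 0.0]])]
        f2 = [np.array([[0.0, 2.25, 0.0], [0.0, -2.25, 0.0]])]
        pa = compute_prdf(f1, single_sphere, "K+", r_max=2.0)
        pb = compute_prdf(f2, single_sphere, "K+", r_max=2.0)
        pm = compute_prdf(f1 + f2, single_sphere, "K+", r_max=2.0)
        assert np.allclose(pm.g, (pa.g + pb.g) / 2.0, rtol=1e-12)

    def test_frame_reader_xyz_and_blank_separators(self):
        text = "0 0 0\n1 1 1\n\n2 2 2\n"
        frames = read_ion_frames(io.StringIO(text))
        assert len(frames) == 2
        assert frames[0].shape == (2, 3)
        assert frames[1].shape == (1, 3)


class TestSynthesizePRDF:
    def test_flat_when_featureless(self):
        p = synthesize_prdf(
            "SYN", "K+", ProfileParams("polar", peak_height=0.0, depletion_depth=0.0)
        )
        assert np.allclose(p.g, p.g_bulk)

    def test_deterministic_for_seed(self):
        params = ProfileParams("negative", peak_height=0.8, depletion_depth=0.6,
                               noise_sd=0.02)
        a = synthesize_prdf("GLU", "K+", params, seed=42)
        b = synthesize_prdf("GLU", "K+", params, seed=42)
        c = synthesize_prdf("GLU", "K+", params, seed=43)
        assert np.array_equal(a.g, b.g)
        assert not np.array_equal(a.g, c.g)

    def test_negative_residue_sign_pattern(self):
        """A negative side chain enriches K+ and depletes Cl- near the surface."""
        params = ProfileParams("negative", peak_height=0.8, depletion_depth=0.7)
        pk = synthesize_prdf("GLU", "K+", params)
        pc = synthesize_prdf("GLU", "Cl-", params)
        near = pk.r_mid < 5.0
        assert pk.g[near].max() > pk.g_bulk
        assert pc.g[near].min() < pc.g_bulk

    def test_unknown_charge_class_raises(self):
        with pytest.raises(ValueError):
            ProfileParams("zwitterionic")

    def test_relaxes_to_bulk_beyond_15(self):
        params = ProfileParams("hydrophobic", depletion_depth=1.0, decay_length=5.0,
                               noise_sd=0.01)
        p = synthesize_prdf("MET", "K+", params, seed=1)
        far = p.r_mid > 15.0
        assert np.allclose(p.g[far], p.g_bulk, atol=0.02)


class TestBulkOnset:
    def test_flat_profile_onset_is_first_shell(self):
        r = default_shell_midpoints(45.0)
        p = PRDF("K+", "SYN", r, np.ones_like(r))
        assert bulk_onset(p) == 0.25

    def test_constructed_onset_at_12(self):
        r = default_shell_midpoints(45.0)
        g = np.where(r < 12.0, 1.5, 1.0)
        p = PRDF("K+", "SYN", r, g)
        assert abs(bulk_onset(p) - 12.0) <= 0.5

    def test_never_bulk_gives_inf(self):
        r = default_shell_midpoints(10.0)
        p = PRDF("K+", "SYN", r, np.full_like(r, 2.0))
        assert bulk_onset(p) == np.inf

    def test_all_fixture_profiles_reach_bulk_by_15(self):
        prdfs = fixture_prdfs(seed=1)
        assert len(prdfs) == 40
        for p in prdfs.values():
            assert bulk_onset(p, rel_tol=0.05) <= 15.0


class TestFixtureTable:
    def test_covers_all_residues_and_species(self):
        params = load_fixture_params()
        assert len(params) == 40
        residues = {r for r, _ in params}
        assert len(residues) == 20

    def test_rows_are_mutually_distinct(self):
        """No two residues share a profile, for either ion species."""
        params = load_fixture_params()
        for species in ("K+", "Cl-"):
            rows = {
                (p.charge_class, p.peak_height, p.peak_pos, p.peak_width,
                 p.depletion_depth, p.decay_length)
                for (r, sp), p in params.items()
                if sp == species
            }
            assert len(rows) == 20

    def test_depletion_profiles_imply_ion_deficit(self, glu):
        """Volume-weighted excess is negative for pure-depletion profiles and
        larger for the attracted than the repelled species of a charged
        residue."""
        prdfs = fixture_prdfs(seed=1)
        vols = np.array(
            [shell_volume(glu, k * 0.5, (k + 1) * 0.5, 0.25) for k in range(30)]
        )

        def excess(p):
            return float(np.sum((p.g[:30] - p.g_bulk) * vols))

        met_k = excess(prdfs[("MET", "K+")])
        met_cl = excess(prdfs[("MET", "Cl-")])
        assert met_k < 0 and met_cl < 0  # hydrophobic depletes both
        assert excess(prdfs[("GLU", "Cl-")]) < 0  # co-ion depleted
        assert excess(prdfs[("GLU", "K+")]) > excess(prdfs[("GLU", "Cl-")])
        assert excess(prdfs[("LYS", "Cl-")]) > excess(prdfs[("LYS", "K+")])


class TestCSVRoundTrip:
    def test_prdf_csv_preserves_profile(self, tmp_path):
        params = ProfileParams("positive", peak_height=0.9, depletion_depth=0.8,
                               noise_sd=0.01)
        p = synthesize_prdf("LYS", "Cl-", params, seed=5)
        path = tmp_path / "lys_cl.csv"
        p.to_csv(path)
        q = PRDF.from_csv(path)
        assert q.species == "Cl-"
        assert q.residue_code == "LYS"
        assert np.allclose(q.g, p.g, atol=1e-6)
        assert np.allclose(q.r_mid, p.r_mid)
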