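"""Superposition, RMSD/RMSF and histogram behaviour against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from fpdyn import geometry as geo
from fpdyn.model import AtomSelection

from conftest import toy_trajectory

ALL = AtomSelection(name="CA")


def brute_force_rotation_rmsd(mobile, reference, n_steps=48, n_refine=6):
    """Independent oracle: exhaustive coarse search over ZYZ Euler angles
    followed by grid zooming around the best cell."""
    from scipy.spatial.transform import Rotation
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def evaluate(euler):
        mats = Rotation.from_euler("ZYZ", euler).as_matrix()  # (M, 3, 3)
        rotated = np.einsum("mij,nj->mni", mats, mob)
        rmsd = np.sqrt(np.mean(np.sum((rotated - ref[None]) ** 2, axis=-1), axis=-1))
        k = int(np.argmin(rmsd))
        return euler[k], float(rmsd[k])

    angles = np.linspace(0, 2 * np.pi, n_steps, endpoint=False)
    betas = np.linspace(0, np.pi, n_steps // 2 + 1)
    aa, bb, cc = np.meshgrid(angles, betas, angles, indexing="ij")
    best, best_rmsd = evaluate(np.column_stack([aa.ravel(), bb.ravel(), cc.ravel()]))
    delta = 2 * np.pi / n_steps
    for _ in range(n_refine):
        offs = np.linspace(-delta, delta, 9)
        oa, ob, oc = np.meshgrid(offs, offs, offs, indexing="ij")
        local = best[None, :] + np.column_stack([oa.ravel(), ob.ravel(), oc.ravel()])
        cand, cand_rmsd = evaluate(local)
        if cand_rmsd < best_rmsd:
            best, best_rmsd = cand, cand_rmsd
        delta /= 4.0
    return best_rmsd


class TestKabsch:
    def test_identical_sets_give_zero_and_identity(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        res = geo.kabsch(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(7, 3))
        from scipy.spatial.transform import Rotation
        r = Rotation.from_rotvec([0.4, -1.2, 0.7]).as_matrix()
        moved = pts @ r.T + np.array([1.0, -2.0, 0.5])
        res = geo.kabsch(moved, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.apply(moved), pts, atol=1e-10)

    def test_matches_rotation_grid_search_oracle(self):
        # 4-point toy set with one point displaced: the closed-form optimum
        # must match exhaustive search over rotation space
        reference = np.array([[0.0, 0, 0], [0.5, 0, 0], [0, 0.5, 0], [0, 0, 0.5]])
        mobile = reference.copy()
        mobile[3] += np.array([0.15, -0.1, 0.2])
        got = geo.kabsch(mobile, reference).rmsd
        oracle = brute_force_rotation_rmsd(mobile, reference)
        assert got <= oracle + 1e-9  # closed form cannot be worse than the grid
        assert got == pytest.approx(oracle, abs=5e-3)  # grid resolution

    def test_count_mismatch_and_degenerate_inputs_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        with pytest.raises(ValueError, match="mismatch"):
            geo.kabsch(pts, pts[:2])
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            geo.kabsch(line, line)

    def test_angstrom_reporting(self):
        pts = np.array([[0.0, 0, 0], [0.5, 0, 0], [0, 0.5, 0], [0, 0, 0.5]])
        moved = pts + np.array([[0, 0, 0], [0, 0, 0], [0, 0, 0], [0.02, 0, 0]])
        res = geo.kabsch(moved, pts)
        assert res.rmsd_angstrom == pytest.approx(res.rmsd * 10)


class TestRmsdSeries:
    def test_copies_of_reference_give_zero(self):
        base = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.3, 0.7]])
        traj = toy_trajectory(np.stack([base] * 4))
        s = geo.rmsd_series(traj, traj.frame(0), ALL, ALL)
        np.testing.assert_allclose(s.values, 0.0, atol=1e-10)

    def test_forced_displacement_of_measured_atom(self):
        # fit atoms immobile; one measured atom displaced by d in one frame
        base = np.zeros((5, 3))
        base[:4] = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]
        base[4] = [0.5, 0.5, 0.5]
        moved = base.copy()
        d = 0.25
        moved[4, 0] += d
        traj = toy_trajectory(np.stack([base, moved]))
        fit = AtomSelection(name="CA", res_id=(1, 4))
        measure = AtomSelection(name="CA", res_id=5)
        s = geo.rmsd_series(traj, traj.frame(0), fit, measure)
        assert s.values[0] == pytest.approx(0.0, abs=1e-12)
        assert s.values[1] == pytest.approx(d, abs=1e-9)


class TestRmsf:
    def test_static_trajectory_gives_zero(self):
        base = np.random.default_rng(1).normal(size=(6, 3))
        traj = toy_trajectory(np.stack([base] * 5))
        prof = geo.rmsf(traj, ALL, ALL)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_single_frame_rejected(self):
        traj = toy_trajectory(np.random.default_rng(2).normal(size=(1, 4, 3)))
        with pytest.raises(ValueError, match="two frames"):
            geo.rmsf(traj, ALL, ALL)

    def test_alternating_atom_has_rmsf_d(self):
        base = np.zeros((5, 3))
        base[:4] = [[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]]
        frames = []
        d = 0.1
        for i in range(40):
            f = base.copy()
            f[4, 2] = d if i % 2 == 0 else -d
            frames.append(f)
        traj = toy_trajectory(np.stack(frames))
        fit = AtomSelection(name="CA", res_id=(1, 4))
        prof = geo.rmsf(traj, ALL, fit)
        np.testing.assert_allclose(prof.values[:4], 0.0, atol=1e-9)
        assert prof.values[4] == pytest.approx(d, rel=1e-6)

    def test_isotropic_jitter_converges_to_sigma_sqrt3(self):
        # Monte-Carlo vs the closed form: per-coordinate sd sigma -> sqrt(3)*sigma
        rng = np.random.default_rng(3)
        sigma = 0.02
        base = np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2], [1, 1, 1]])
        n = 4000
        frames = np.stack([base] * n)
        frames[:, 4] += rng.normal(0, sigma, size=(n, 3))
        traj = toy_trajectory(frames)
        fit = AtomSelection(name="CA", res_id=(1, 4))
        prof = geo.rmsf(traj, AtomSelection(name="CA", res_id=5), fit)
        assert prof.values[0] == pytest.approx(sigma * np.sqrt(3), rel=0.05)


class TestDeltaRmsf:
    def test_profile_minus_itself_is_zero(self):
        p = geo.FluctuationProfile(("a", "b"), np.array([0.1, 0.2]))
        np.testing.assert_allclose(geo.delta_rmsf(p, p).values, 0.0)

    def test_printed_chromophore_flux_difference(self):
        # mCherry CRO 0.11 nm vs mCoral 0.051 nm -> difference 0.059 nm
        mcherry = geo.FluctuationProfile(("CRO",), np.array([0.11]))
        mcoral = geo.FluctuationProfile(("CRO",), np.array([0.051]))
        d = geo.delta_rmsf(mcherry, mcoral)
        assert d.values[0] == pytest.approx(0.059)

    def test_antisymmetry_and_key_mismatch(self):
        a = geo.FluctuationProfile(("x", "y"), np.array([0.3, 0.1]))
        b = geo.FluctuationProfile(("x", "y"), np.array([0.05, 0.4]))
        np.testing.assert_allclose(
            geo.delta_rmsf(a, b).values, -geo.delta_rmsf(b, a).values
        )
        c = geo.FluctuationProfile(("x", "z"), np.array([0.0, 0.0]))
        with pytest.raises(ValueError, match="z"):
            geo.delta_rmsf(a, c)


class TestPairDistance:
    def test_fixed_distance_and_coincident_atoms(self):
        coords = np.zeros((3, 2, 3))
        coords[:, 1, 0] = 1.1
        traj = toy_trajectory(coords)
        s = geo.pair_distance_series(
            traj, AtomSelection(res_id=1), AtomSelection(res_id=2)
        )
        np.testing.assert_allclose(s.values, 1.1)
        coincident = toy_trajectory(np.zeros((2, 2, 3)))
        s0 = geo.pair_distance_series(
            coincident, AtomSelection(res_id=1), AtomSelection(res_id=2)
        )
        np.testing.assert_allclose(s0.values, 0.0)

    def test_multi_atom_selection_rejected(self):
        traj = toy_trajectory(np.zeros((1, 3, 3)))
        from fpdyn.model import SelectionError
        with pytest.raises(SelectionError, match="exactly one"):
            geo.pair_distance_series(traj, ALL, AtomSelection(res_id=1))


class TestHistogram:
    def test_constant_series_single_bin(self):
        s = geo.SeriesStat(np.arange(5.0), np.full(5, 0.83))
        h = geo.histogram(s, 0.1)
        assert h.counts.sum() == 5
        assert (h.counts > 0).sum() == 1
        assert h.mode_center == pytest.approx(0.85)

    def test_forced_counts_and_mode(self):
        s = geo.SeriesStat(np.arange(3.0), np.array([0.05, 0.15, 0.15]))
        h = geo.histogram(s, 0.1)
        np.testing.assert_array_equal(h.counts, [1, 2])
        assert h.mode_center == pytest.approx(0.15)

    def test_mode_tie_breaks_to_lower_bin(self):
        s = geo.SeriesStat(np.arange(4.0), np.array([0.05, 0.05, 0.25, 0.25]))
        h = geo.histogram(s, 0.1)
        assert h.mode_center == pytest.approx(0.05)

    def test_invalid_inputs(self):
        s = geo.SeriesStat(np.arange(2.0), np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            geo.histogram(s, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(
        values=st_.lists(st_.floats(0.0, 5.0), min_size=1, max_size=100),
        width=st_.floats(0.01, 1.0),
    )
    def test_counts_conserved_and_mode_populated(self, values, width):
        s = geo.SeriesStat(np.arange(float(len(values))), np.array(values))
        h = geo.histogram(s, width)
        assert h.counts.sum() == len(values)
        populated = h.centers[h.counts > 0]
        assert h.mode_center in populated
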