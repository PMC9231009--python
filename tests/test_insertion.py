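"""Insertion scoring: plane fits, classification, gating, Ip/IS, descriptors."""

import numpy as np
import pytest

from toxmem import insertion as ins
from toxmem import synthetic as syn
from toxmem.trajectory import Trajectory


def brute_force_insertion(traj, criterion="residue_com", gate_nm=0.5):
    """Naive per-frame, per-residue reimplementation used as the oracle."""
    F, R = traj.n_frames, traj.n_residues
    mat = np.zeros((F, R), dtype=bool)
    onset = None
    for f in range(F):
        heads = traj.upper_heads[f]
        A = np.column_stack([heads[:, 0], heads[:, 1], np.ones(len(heads))])
        a, b, c = np.linalg.lstsq(A, heads[:, 2], rcond=None)[0]
        com = traj.toxin_com()[f]
        if onset is None and com[2] - (a * com[0] + b * com[1] + c) < gate_nm:
            onset = f
        if onset is None:
            continue
        ref = traj.sidechain_com[f] if criterion == "sidechain_com" else traj.residue_com[f]
        for r in range(R):
            surf = a * ref[r, 0] + b * ref[r, 1] + c
            mat[f, r] = ref[r, 2] < surf
    return mat, (onset if onset is not None else ins.NO_ONSET)


def simple_traj(res_xyz, head_z=2.0, n_heads=16, times=None, masses=None):
    """Trajectory with a flat grid of heads at head_z and given residue coords."""
    res_xyz = np.asarray(res_xyz, dtype=float)
    F = res_xyz.shape[0]
    g = np.linspace(1.0, 9.0, int(np.sqrt(n_heads)))
    xy = np.stack(np.meshgrid(g, g), axis=-1).reshape(-1, 2)
    upper = np.concatenate([xy, np.full((len(xy), 1), head_z)], axis=1)
    lower = upper.copy()
    lower[:, 2] = -head_z
    return Trajectory(
        times=np.arange(F, dtype=float) if times is None else times,
        box=np.tile([10.0, 10.0, 8.0], (F, 1)),
        upper_heads=np.tile(upper, (F, 1, 1)),
        lower_heads=np.tile(lower, (F, 1, 1)),
        residue_com=res_xyz,
        residue_masses=masses,
    )


class TestFitLeaflet:
    def test_flat_grid_recovers_horizontal_plane(self):
        g = np.linspace(0, 10, 5)
        xy = np.stack(np.meshgrid(g, g), axis=-1).reshape(-1, 2)
        heads = np.concatenate([xy, np.full((25, 1), 2.0)], axis=1)
        fit = ins.fit_leaflet(heads)
        assert (fit.a, fit.b, fit.c) == pytest.approx((0.0, 0.0, 2.0), abs=1e-12)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_exact_tilted_plane(self):
        g = np.linspace(0, 10, 5)
        xy = np.stack(np.meshgrid(g, g), axis=-1).reshape(-1, 2)
        z = 0.1 * xy[:, 0] + 1.0
        fit = ins.fit_leaflet(np.column_stack([xy, z]))
        assert (fit.a, fit.b, fit.c) == pytest.approx((0.1, 0.0, 1.0), abs=1e-12)

    def test_noisy_tilted_plane_within_three_se(self):
        rng = np.random.default_rng(0)
        g = np.linspace(0, 10, 12)
        xy = np.stack(np.meshgrid(g, g), axis=-1).reshape(-1, 2)
        z = 0.05 * xy[:, 0] - 0.03 * xy[:, 1] + 1.5 + rng.normal(0, 0.05, len(xy))
        fit = ins.fit_leaflet(np.column_stack([xy, z]))
        # standard error of a slope with sigma=0.05 over this grid is ~4e-4
        assert fit.a == pytest.approx(0.05, abs=3 * 4e-4)
        assert fit.b == pytest.approx(-0.03, abs=3 * 4e-4)

    def test_collinear_heads_rejected(self):
        heads = np.column_stack([np.arange(5.0), np.arange(5.0), np.ones(5)])
        with pytest.raises(ins.InsertionError):
            ins.fit_leaflet(heads)


class TestGateOnset:
    def test_first_frame_below_half_nm(self):
        # COM-to-plane distances: 3.0, 1.0, 0.4, 0.2
        z = np.array([5.0, 3.0, 2.4, 2.2])
        res = np.zeros((4, 1, 3))
        res[:, 0, :2] = 5.0
        res[:, 0, 2] = z
        traj = simple_traj(res)
        assert ins.gate_onset(traj) == 2

    def test_never_within_gate_is_sentinel(self):
        res = np.zeros((3, 1, 3))
        res[:, 0, :2] = 5.0
        res[:, 0, 2] = [5.0, 4.0, 3.0]
        traj = simple_traj(res)
        assert ins.gate_onset(traj) == ins.NO_ONSET

    def test_distance_series_gate_examples(self):
        assert ins.first_within_gate(np.array([3.0, 1.0, 0.4, 0.2])) == 2
        assert ins.first_within_gate(np.array([3.0, 1.0, 0.6])) == ins.NO_ONSET

    def test_exactly_at_gate_is_not_onset(self):
        # the contact criterion is a strict inequality
        assert ins.first_within_gate(np.array([3.0, 0.5])) == ins.NO_ONSET
        assert ins.first_within_gate(np.array([3.0, np.nextafter(0.5, 0.0)])) == 1


class TestClassify:
    def test_residue_above_plane_not_inserted(self):
        res = np.zeros((2, 1, 3))
        res[:, 0, :2] = 5.0
        res[:, 0, 2] = [2.3, 2.2]  # within gate, above plane
        traj = simple_traj(res)
        mat = ins.classify_insertions(traj)
        assert not mat.inserted.any()

    def test_oracle_agreement_zero_roughness(self, patch_trajectory):
        mat = ins.classify_insertions(patch_trajectory)
        ref, onset = brute_force_insertion(patch_trajectory)
        assert mat.onset_frame == onset == 5
        np.testing.assert_array_equal(mat.inserted, ref)
        np.testing.assert_array_equal(mat.inserted, patch_trajectory.ground_truth_insertion)

    def test_oracle_agreement_rough_bilayer(self, rough_bilayer, snx482):
        rng = np.random.default_rng(11)
        depths = rng.uniform(-0.4, 0.4, 41)
        sc = syn.BindingScenario(target_depths=depths, onset_frame=10, depth_noise_sigma=0.2, seed=5)
        traj = syn.make_binding_trajectory(rough_bilayer, sc, snx482)
        mat = ins.classify_insertions(traj)
        ref, onset = brute_force_insertion(traj)
        assert mat.onset_frame == onset
        np.testing.assert_array_equal(mat.inserted, ref)

    def test_sidechain_criterion_differs_from_residue_com(self):
        res = np.zeros((2, 1, 3))
        res[:, 0, :2] = 5.0
        res[:, 0, 2] = 1.9        # residue COM below plane (and within gate)
        traj = simple_traj(res)
        traj.sidechain_com = res.copy()
        traj.sidechain_com[:, 0, 2] = 2.3  # side-chain COM above plane
        by_com = ins.classify_insertions(traj, "residue_com")
        by_sc = ins.classify_insertions(traj, "sidechain_com")
        assert by_com.inserted.all()
        assert not by_sc.inserted.any()

    def test_below_c1_stricter_than_residue_com(self):
        res = np.zeros((2, 1, 3))
        res[:, 0, :2] = 5.0
        res[:, 0, 2] = 1.9          # below heads (2.0) but above C1 plane (1.6)
        traj = simple_traj(res)
        traj.c1_upper_z = np.full((2, traj.upper_heads.shape[1]), 1.6)
        assert ins.classify_insertions(traj, "residue_com").inserted.all()
        assert not ins.classify_insertions(traj, "below_c1").inserted.any()

    def test_missing_data_raises_with_column_name(self):
        res = np.zeros((2, 1, 3))
        traj = simple_traj(res)
        with pytest.raises(ins.InsertionError, match="sidechain_com"):
            ins.classify_insertions(traj, "sidechain_com")

    def test_rigid_translation_invariance(self, patch_trajectory):
        ref = ins.classify_insertions(patch_trajectory).inserted
        t = patch_trajectory
        shift = np.array([3.0, -2.0, 1.7])
        moved = Trajectory(
            times=t.times,
            box=t.box,
            upper_heads=t.upper_heads + shift,
            lower_heads=t.lower_heads + shift,
            residue_com=t.residue_com + shift,
            residue_masses=t.residue_masses,
        )
        np.testing.assert_array_equal(ins.classify_insertions(moved).inserted, ref)


class TestIpAndIS:
    def test_ip_is_fraction_of_window_frames(self):
        mat = ins.InsertionMatrix(
            inserted=np.array([[True]] * 6 + [[False]] * 4), criterion="residue_com", onset_frame=0
        )
        prof = ins.insertion_probability(mat, window=(0, 10))
        assert prof.ip[0] == pytest.approx(0.6)

    def test_all_false_and_all_true(self):
        for value, expect in ((False, 0.0), (True, 1.0)):
            mat = ins.InsertionMatrix(np.full((8, 3), value), "residue_com", 0)
            prof = ins.insertion_probability(mat)
            assert np.all(prof.ip == expect)

    def test_is_sums_ip(self):
        prof = ins.InsertionProfile(
            ip=np.concatenate([np.full(10, 0.5), np.zeros(31)]), window=(0, 10), n_residues=41
        )
        assert ins.insertion_score(prof) == pytest.approx(5.0)

    def test_is_saturates_at_41(self, flat_bilayer, snx482):
        sc = syn.BindingScenario(target_depths=np.full(41, -0.5), onset_frame=5, depth_noise_sigma=0.0)
        traj = syn.make_binding_trajectory(flat_bilayer, sc, snx482)
        mat = ins.classify_insertions(traj)
        assert ins.insertion_score(ins.insertion_probability(mat)) == 41.0

    def test_empty_window_rejected(self):
        mat = ins.InsertionMatrix(np.zeros((5, 2), dtype=bool), "residue_com", 0)
        with pytest.raises(ins.InsertionError):
            ins.insertion_probability(mat, window=(3, 3))

    def test_window_before_onset_rejected(self):
        mat = ins.InsertionMatrix(np.zeros((10, 2), dtype=bool), "residue_com", 4)
        with pytest.raises(ins.InsertionError):
            ins.insertion_probability(mat, window=(0, 10))

    def test_merged_window_is_frame_weighted_mean(self):
        rng = np.random.default_rng(3)
        mat = ins.InsertionMatrix(rng.random((30, 5)) < 0.4, "residue_com", 0)
        full = ins.insertion_probability(mat, (0, 30)).ip
        a = ins.insertion_probability(mat, (0, 10)).ip
        b = ins.insertion_probability(mat, (10, 30)).ip
        np.testing.assert_allclose(full, (10 * a + 20 * b) / 30, atol=1e-12)


class TestISTimeDerivative:
    def test_exact_slope_on_collinear_windows(self, flat_bilayer, snx482):
        # linearly deepening insertion: residues cross the plane one frame at a time
        F = flat_bilayer.spec.n_frames
        sc = syn.BindingScenario(target_depths=np.full(41, -0.5), onset_frame=2, depth_noise_sigma=0.0)
        traj = syn.make_binding_trajectory(flat_bilayer, sc, snx482)
        slope, mids, values = ins.is_time_derivative(traj, window_ns=6.0)
        # constant full insertion per window -> slope 0
        assert values == pytest.approx([41.0] * len(values))
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_ols_slope_units_per_microsecond(self):
        # three window IS values 10, 11, 12 spaced 0.5 us apart -> 2 IS/us
        t = np.polyfit([250.0, 750.0, 1250.0], [10.0, 11.0, 12.0], 1)[0] * 1e3
        assert t == pytest.approx(2.0)


class TestPlateauAndDescriptors:
    def test_plateau_found_near_onset(self, flat_bilayer, snx482):
        sc = syn.BindingScenario(target_depths=np.full(41, -0.5), onset_frame=8, depth_noise_sigma=0.0)
        traj = syn.make_binding_trajectory(flat_bilayer, sc, snx482)
        _, plateau = ins.com_distance_and_plateau(traj, slope_tol=1e-3, window=5)
        assert 0 <= plateau <= 9

    def test_strict_decrease_has_no_plateau(self):
        res = np.zeros((20, 1, 3))
        res[:, 0, :2] = 5.0
        res[:, 0, 2] = np.linspace(6.0, 3.0, 20)
        traj = simple_traj(res)
        with pytest.warns(UserWarning):
            _, plateau = ins.com_distance_and_plateau(traj, slope_tol=1e-4, window=5)
        assert plateau == ins.NO_PLATEAU

    def test_area_per_lipid_and_thickness(self, flat_bilayer, snx482):
        sc = syn.BindingScenario(target_depths=np.full(41, -0.5), onset_frame=5)
        traj = syn.make_binding_trajectory(flat_bilayer, sc, snx482)
        d = ins.membrane_descriptors(traj, 0)
        assert d["area_per_lipid"] == pytest.approx(11.5 * 11.5 / 154)
        assert d["thickness"] == pytest.approx(4.0)


class TestAxialDensity:
    def _traj_with_ions(self, ion_z, n_frames=4):
        res = np.zeros((n_frames, 1, 3))
        res[:, 0, 2] = 6.0
        res[:, 0, :2] = 5.0
        traj = simple_traj(res)
        ions = np.zeros((n_frames, len(ion_z), 3))
        ions[:, :, 2] = ion_z
        traj.ions = ions
        return traj

    def test_fixed_ions_single_bin(self):
        traj = self._traj_with_ions([0.0, 0.0, 0.0])
        centers, dens = ins.axial_density(traj, "ion", bin_width=0.1)
        assert (dens > 0).sum() == 1

    def test_density_integrates_to_mean_count(self):
        rng = np.random.default_rng(1)
        traj = self._traj_with_ions(rng.uniform(-3, 3, 30))
        centers, dens = ins.axial_density(traj, "ion", bin_width=0.2)
        area = 10.0 * 10.0
        assert dens.sum() * 0.2 * area == pytest.approx(30.0)

    def test_unknown_species_rejected(self):
        traj = self._traj_with_ions([0.0])
        with pytest.raises(ins.InsertionError):
            ins.axial_density(traj, "cholesterol")
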