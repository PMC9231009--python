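"""MSD, Einstein fits, and the periodic finite-size correction."""

import numpy as np
import pytest

from toxmem import diffusion as dif
from toxmem import synthetic as syn


def brute_force_msd(positions, max_lag):
    """All-origins MSD by explicit double loop (the oracle)."""
    n = len(positions)
    out = np.zeros(max_lag + 1)
    for m in range(max_lag + 1):
        disps = [
            np.sum((positions[t0 + m] - positions[t0]) ** 2) for t0 in range(n - m)
        ]
        out[m] = np.mean(disps)
    return out


class TestMSD:
    def test_matches_brute_force_on_ten_frames(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(size=(10, 3))
        t = np.arange(10.0)
        curve = dif.msd(pos, t, max_lag_fraction=1.0)
        np.testing.assert_allclose(curve.msd_nm2, brute_force_msd(pos, 9), atol=1e-10)
        np.testing.assert_array_equal(curve.n_pairs, 10 - np.arange(10))

    def test_ballistic_motion_quadratic_all_origins(self):
        v = 0.3
        t = np.arange(10.0)
        pos = np.column_stack([v * t, np.zeros(10), np.zeros(10)])
        curve = dif.msd(pos, t, max_lag_fraction=1.0)
        np.testing.assert_allclose(curve.msd_nm2, (v * curve.lag_times_ns) ** 2, atol=1e-12)

    def test_static_positions_zero(self):
        pos = np.ones((20, 2))
        curve = dif.msd(pos, np.arange(20.0))
        np.testing.assert_allclose(curve.msd_nm2, 0.0, atol=1e-14)

    def test_single_origin_collapses_to_naive_displacement(self):
        rng = np.random.default_rng(1)
        pos = rng.normal(size=(12, 2))
        curve = dif.msd(pos, np.arange(12.0), origin_stride=len(pos), max_lag_fraction=1.0)
        expected = np.sum((pos - pos[0]) ** 2, axis=1)
        np.testing.assert_allclose(curve.msd_nm2, expected, atol=1e-12)

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(2)
        pos = rng.normal(size=(50, 3)).cumsum(axis=0)
        t = np.arange(50.0)
        base = dif.msd(pos, t).msd_nm2
        shifted = dif.msd(pos + np.array([5.0, -2.0, 9.0]), t).msd_nm2
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        rotated = dif.msd(pos @ R.T, t).msd_nm2
        np.testing.assert_allclose(shifted, base, atol=1e-9)
        np.testing.assert_allclose(rotated, base, atol=1e-9)

    def test_wrapped_coordinates_detected(self):
        pos = np.zeros((10, 2))
        pos[5] = [4.0, 0.0]  # jump > box/2 for a 6 nm box
        with pytest.raises(dif.DiffusionError, match="unwrap"):
            dif.msd(pos, np.arange(10.0), box_lengths=np.array([6.0, 6.0]))


class TestEinsteinFit:
    def test_exact_line_3d(self):
        lags = np.linspace(0, 10, 50)
        curve = dif.MSDCurve(lags, 6.0 * lags, np.full(50, 100), 3)
        est = dif.einstein_fit(curve)
        assert est.D_cm2_s == pytest.approx(1.0e-5, rel=1e-9)

    def test_exact_line_2d(self):
        lags = np.linspace(0, 10, 50)
        curve = dif.MSDCurve(lags, 4.0 * lags, np.full(50, 100), 2)
        est = dif.einstein_fit(curve)
        assert est.D_cm2_s == pytest.approx(1.0e-5, rel=1e-9)

    def test_unbiased_on_noisy_lines(self):
        # MSD = 2 d D tau + zero-mean noise: repeat-seed mean recovers D
        rng = np.random.default_rng(3)
        d_true = 2.0e-6  # cm^2/s -> slope 2*2*0.2 nm^2/ns in 2D
        lags = np.linspace(0, 5, 40)
        ests = []
        for _ in range(200):
            msd_vals = 2 * 2 * (d_true * 1e5) * lags + rng.normal(0, 0.05, 40)
            curve = dif.MSDCurve(lags, msd_vals, np.full(40, 100), 2)
            ests.append(dif.einstein_fit(curve).D_cm2_s)
        sem = np.std(ests) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(d_true, abs=2 * sem)

    def test_brownian_parameter_recovery(self):
        for d_true, ndim in ((1.0e-6, 3), (4.1e-8, 2)):
            t, pos = syn.make_brownian(
                syn.BrownianSpec(D=d_true, n_dims=ndim, n_steps=200_000, seed=9)
            )
            curve = dif.msd(pos, t, max_lag_fraction=0.002)
            est = dif.einstein_fit(curve)
            assert est.D_cm2_s == pytest.approx(d_true, rel=0.10)

    def test_window_outside_curve_rejected(self):
        curve = dif.MSDCurve(np.array([0.0, 1.0]), np.array([0.0, 1.0]), np.array([2, 1]), 2)
        with pytest.raises(dif.DiffusionError):
            dif.einstein_fit(curve, fit_window=(0.9, 0.91))


class TestPSD:
    def test_large_box_limit_no_correction(self):
        d_inf, delta = dif.psd_extrapolate(4.1e-8, dif.PSDInputs(box_L_nm=1e6))
        assert d_inf == pytest.approx(4.1e-8, rel=1e-3)
        assert delta >= 0

    def test_halving_box_increases_correction(self):
        deltas = [
            dif.psd_correction(dif.PSDInputs(box_L_nm=L)) for L in (32.0, 16.0, 8.0)
        ]
        assert deltas[0] < deltas[1] < deltas[2]

    def test_correction_nonnegative_and_additive(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            inputs = dif.PSDInputs(
                box_L_nm=float(rng.uniform(5, 500)),
                membrane_viscosity=float(rng.uniform(1e-11, 1e-8)),
                water_viscosity=float(rng.uniform(3e-4, 3e-3)),
                inclusion_radius_nm=1.0,
            )
            d_inf, delta = dif.psd_extrapolate(4.1e-8, inputs)
            assert delta >= 0
            assert d_inf == pytest.approx(4.1e-8 + delta)

    def test_nonphysical_inputs_rejected(self):
        with pytest.raises(dif.DiffusionError):
            dif.PSDInputs(box_L_nm=-1.0)
        with pytest.raises(dif.DiffusionError):
            dif.psd_extrapolate(0.0, dif.PSDInputs())
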