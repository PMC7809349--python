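"""Spectrum inversion: NNLS, chi-square regularization, flip-angle search,
MWF readout and volume fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import nnls_bruteforce

from mwimap.epg import T2Grid, decay_basis, epg_decay
from mwimap.t2spectrum import (T2Spectrum, estimate_flip_angle, fit_mwf_signal,
                               fit_mwf_volume, mwf_from_spectrum,
                               nnls_regularized, nnls_solve)


def two_pool_signal(spec, f=0.15, alpha=171.0, t2m=20.0, t2f=80.0):
    return (f * epg_decay(t2m, 450.0, alpha, spec)
            + (1 - f) * epg_decay(t2f, 1000.0, alpha, spec))


def add_rician(signal, snr, rng):
    sigma = signal[0] / snr
    return np.abs(signal + sigma * rng.standard_normal(signal.shape)
                  + 1j * sigma * rng.standard_normal(signal.shape))


class TestNnlsSolve:
    def test_recovers_consistent_sparse_solution(self, cord_spec, grid):
        basis = decay_basis(grid, 160.0, cord_spec)
        s_true = np.zeros(grid.n_points)
        s_true[[3, 20]] = [0.2, 0.8]
        amp, resid = nnls_solve(basis, basis @ s_true)
        assert resid < 1e-16
        assert np.allclose(amp, s_true, atol=1e-6)

    def test_zero_signal_gives_zero_spectrum(self, cord_spec, grid):
        basis = decay_basis(grid, 160.0, cord_spec)
        amp, resid = nnls_solve(basis, np.zeros(cord_spec.n_echoes))
        assert np.all(amp == 0) and resid == 0

    def test_matches_support_enumeration_oracle(self, rng):
        for _ in range(8):
            A = rng.uniform(0, 1, (10, 5))
            x0 = np.zeros(5)
            x0[rng.integers(0, 5, size=2)] = rng.uniform(0, 1, 2)
            y = A @ x0 + 0.05 * rng.standard_normal(10)
            amp, resid = nnls_solve(A, y)
            amp_b, resid_b = nnls_bruteforce(A, y)
            assert resid == pytest.approx(resid_b, abs=1e-10)
            assert np.allclose(amp, amp_b, atol=1e-7)

    def test_dimension_mismatch(self, cord_spec, grid):
        basis = decay_basis(grid, 160.0, cord_spec)
        with pytest.raises(ValueError):
            nnls_solve(basis, np.ones(cord_spec.n_echoes + 1))


class TestNnlsRegularized:
    def test_ratio_lands_in_declared_band(self, cord_spec, grid, rng):
        basis = decay_basis(grid, 165.0, cord_spec)
        for _ in range(10):
            noisy = add_rician(two_pool_signal(cord_spec), 100, rng)
            amp, mu, chi2 = nnls_regularized(basis, noisy, 1.02)
            _, chi2_min = nnls_solve(basis, noisy)
            assert 1.02 <= chi2 / chi2_min <= 1.025
            assert mu > 0 and np.all(amp >= 0)

    def test_factor_one_is_plain_nnls(self, cord_spec, grid, rng):
        basis = decay_basis(grid, 165.0, cord_spec)
        noisy = add_rician(two_pool_signal(cord_spec), 100, rng)
        amp0, chi2_min = nnls_solve(basis, noisy)
        amp, mu, chi2 = nnls_regularized(basis, noisy, 1.0)
        assert mu == 0.0 and chi2 == pytest.approx(chi2_min)
        assert np.allclose(amp, amp0)

    def test_noiseless_consistent_data_falls_back_unregularized(
            self, cord_spec, grid):
        basis = decay_basis(grid, 165.0, cord_spec)
        s_true = np.zeros(grid.n_points)
        s_true[[5, 22]] = [0.3, 0.7]
        amp, mu, chi2 = nnls_regularized(basis, basis @ s_true, 1.02)
        assert mu == 0.0 and chi2 < 1e-15

    def test_chi2_monotone_in_mu(self, cord_spec, grid, rng):
        basis = decay_basis(grid, 165.0, cord_spec)
        noisy = add_rician(two_pool_signal(cord_spec), 100, rng)
        n = grid.n_points
        chis = []
        for mu in np.geomspace(1e-4, 1e3, 15):
            aug = np.vstack([basis, mu * np.eye(n)])
            amp, _ = nnls_solve(aug, np.concatenate([noisy, np.zeros(n)]))
            r = basis @ amp - noisy
            chis.append(r @ r)
        assert np.all(np.diff(chis) >= -1e-12)
        # mu -> inf drives the spectrum to zero and chi2 to the signal energy
        assert chis[-1] == pytest.approx(noisy @ noisy, rel=1e-3)

    def test_invalid_factor(self, cord_spec, grid):
        basis = decay_basis(grid, 165.0, cord_spec)
        with pytest.raises(ValueError):
            nnls_regularized(basis, np.ones(cord_spec.n_echoes), 0.9)


class TestEstimateFlipAngle:
    def test_exact_at_perfect_refocusing(self, cord_spec, grid):
        # on-grid T2s and matched T1 make the 180-degree residual exactly
        # zero, so the search must return the boundary exactly
        t = grid.as_array()
        sig = (0.2 * epg_decay(t[2], 1000.0, 180.0, cord_spec)
               + 0.8 * epg_decay(t[20], 1000.0, 180.0, cord_spec))
        assert estimate_flip_angle(sig, grid, cord_spec) == 180.0
        # off-grid tissue: still localized at the boundary within the
        # numerical flatness of the residual
        sig2 = two_pool_signal(cord_spec, alpha=180.0)
        assert estimate_flip_angle(sig2, grid, cord_spec) >= 179.5

    def test_interior_angle_within_half_spacing(self, cord_spec, grid):
        sig = two_pool_signal(cord_spec, alpha=137.0)
        spacing = 90.0 / 7.0
        ahat = estimate_flip_angle(sig, grid, cord_spec)
        assert abs(ahat - 137.0) <= spacing / 2.0

    def test_deterministic(self, cord_spec, grid, rng):
        noisy = add_rician(two_pool_signal(cord_spec), 100, rng)
        a1 = estimate_flip_angle(noisy, grid, cord_spec)
        a2 = estimate_flip_angle(noisy.copy(), grid, cord_spec)
        assert a1 == a2

    def test_all_zero_signal_rejected(self, cord_spec, grid):
        with pytest.raises(ValueError):
            estimate_flip_angle(np.zeros(cord_spec.n_echoes), grid, cord_spec)


class TestMwfFromSpectrum:
    def test_window_arithmetic(self, grid):
        t = grid.as_array()
        amp = np.zeros(grid.n_points)
        amp[np.argmin(np.abs(t - 20.0))] = 1.0
        assert mwf_from_spectrum(T2Spectrum(grid, amp)) == 1.0
        amp2 = np.zeros(grid.n_points)
        amp2[np.argmin(np.abs(t - 100.0))] = 1.0
        assert mwf_from_spectrum(T2Spectrum(grid, amp2)) == 0.0
        amp3 = np.zeros(grid.n_points)
        amp3[np.argmin(np.abs(t - 20.0))] = 0.2
        amp3[np.argmin(np.abs(t - 80.0))] = 0.8
        assert mwf_from_spectrum(T2Spectrum(grid, amp3)) == pytest.approx(0.20)

    def test_grid_point_on_window_edge_excluded(self, grid):
        amp = np.zeros(grid.n_points)
        amp[0] = 1.0  # exactly 15 ms
        assert mwf_from_spectrum(T2Spectrum(grid, amp)) == 0.0

    def test_empty_spectrum(self, grid):
        assert mwf_from_spectrum(T2Spectrum(grid, np.zeros(grid.n_points))) == 0.0

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=20)
    def test_scale_invariance(self, grid, scale):
        rng = np.random.default_rng(7)
        amp = rng.uniform(0, 1, grid.n_points)
        m1 = mwf_from_spectrum(T2Spectrum(grid, amp))
        m2 = mwf_from_spectrum(T2Spectrum(grid, amp * scale))
        assert m1 == pytest.approx(m2, rel=1e-9)


class TestFitMwf:
    def test_single_voxel_noiseless_recovery(self, cord_spec, grid):
        res = fit_mwf_signal(two_pool_signal(cord_spec, f=0.15, alpha=171.0),
                             cord_spec, grid)
        assert abs(res.mwf - 0.15) <= 0.01
        assert abs(res.alpha_hat - 171.0) < 1.0
        assert res.chi2_reg >= res.chi2_min

    def test_signal_scale_invariance(self, cord_spec, grid, rng):
        noisy = add_rician(two_pool_signal(cord_spec), 100, rng)
        r1 = fit_mwf_signal(noisy, cord_spec, grid)
        r2 = fit_mwf_signal(3.7 * noisy, cord_spec, grid)
        assert r1.mwf == pytest.approx(r2.mwf, abs=1e-9)

    def test_volume_mask_and_shapes(self, cord_spec, grid):
        sig = two_pool_signal(cord_spec, f=0.2, alpha=175.0)
        vol = np.zeros((3, 2, 1, cord_spec.n_echoes))
        vol[..., :] = sig
        mask = np.zeros((3, 2, 1), dtype=bool)
        mask[0, 0, 0] = mask[2, 1, 0] = True
        res = fit_mwf_volume(vol, cord_spec, grid, mask=mask)
        assert np.isfinite(res.mwf.data[0, 0, 0])
        assert np.isnan(res.mwf.data[1, 0, 0])
        assert res.mwf.data[0, 0, 0] == pytest.approx(0.2, abs=0.01)
        assert res.qc.data[0, 0, 0] in (0.0, 1.0)

    def test_volume_shape_mismatch(self, cord_spec, grid):
        with pytest.raises(ValueError):
            fit_mwf_volume(np.zeros((2, 2, 1, 5)), cord_spec, grid)
        with pytest.raises(ValueError):
            fit_mwf_volume(np.zeros((2, 2, 1, cord_spec.n_echoes)), cord_spec,
                           grid, mask=np.ones((3, 3, 1), dtype=bool))
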