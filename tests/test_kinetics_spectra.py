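"""SVD analysis and variable-projection global exponential fitting."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from kinemap.kinetics_spectra import (
    SpectraMatrix,
    compute_delta_A,
    fit_single_trace,
    global_exp_fit,
    read_spectra_csv,
    reconstruct,
    select_rank,
    svd_decompose,
    write_spectra_csv,
)


def two_exp_matrix(tau1=10e-6, tau2=1e-3, snr=None, seed=0, n_wl=6, n_t=60):
    """Synthetic decay matrix with two shared time constants."""
    rng = np.random.default_rng(seed)
    times = np.geomspace(1e-6, 10e-3, n_t)
    wl = np.linspace(380, 560, n_wl)
    B1 = np.sin(np.linspace(0, np.pi, n_wl))
    B2 = np.cos(np.linspace(0, np.pi, n_wl))
    dA = np.outer(B1, np.exp(-times / tau1)) + np.outer(B2, np.exp(-times / tau2))
    if snr is not None:
        dA = dA + rng.normal(0, np.abs(dA).max() / snr, dA.shape)
    return SpectraMatrix(wavelengths=wl, times=times, dA=dA)


class TestDeltaA:
    def test_equal_intensities(self):
        I = np.array([1.0, 2.0, 3.0])
        assert np.allclose(compute_delta_A(I, I), 0.0)

    def test_decadic_definition(self):
        I = np.array([10.0, 100.0])
        assert np.allclose(compute_delta_A(I, I / 10), 1.0)

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0.1, 5.0, 20), rng.uniform(0.1, 5.0, 20)
        assert np.allclose(compute_delta_A(a, b), -np.log10(b / a))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            compute_delta_A(np.array([1.0, 0.0]), np.array([1.0, 1.0]))


class TestSVD:
    def test_rank_one_outer_product(self):
        u = np.array([1.0, 2.0, 3.0])
        v = np.array([4.0, 5.0, 6.0, 7.0])
        A = SpectraMatrix(wavelengths=np.arange(3.0), times=np.arange(1.0, 5.0),
                          dA=np.outer(u, v))
        res = svd_decompose(A)
        assert res.S[1] <= 1e-10 * res.S[0]

    def test_diagonal_singular_values(self):
        A = SpectraMatrix(wavelengths=np.arange(2.0), times=np.arange(1.0, 3.0),
                          dA=np.diag([3.0, 1.0]))
        res = svd_decompose(A)
        assert np.allclose(res.S, [3.0, 1.0])

    def test_orthonormality_and_full_reconstruction(self):
        A = two_exp_matrix(snr=20, seed=2)
        res = svd_decompose(A)
        assert np.all(np.diff(res.S) <= 0)
        assert np.allclose(res.U.T @ res.U, np.eye(res.U.shape[1]), atol=1e-8)
        assert np.allclose(res.V.T @ res.V, np.eye(res.V.shape[1]), atol=1e-8)
        assert np.allclose(res.reconstruction(), A.dA, atol=1e-8)

    def test_noise_floor_of_third_singular_value(self):
        """On rank-2 + noise data, s3 stays near the random-matrix noise floor
        (~noise * sqrt(max dim)) while s1, s2 sit far above it."""
        sd = 1e-3
        ratios = []
        for seed in range(50):
            A = two_exp_matrix(seed=seed, n_wl=24)
            rng = np.random.default_rng(seed + 1000)
            A = SpectraMatrix(A.wavelengths, A.times,
                              A.dA + rng.normal(0, sd, A.dA.shape))
            S = svd_decompose(A).S
            floor = sd * np.sqrt(max(A.dA.shape))
            assert S[1] > 5 * floor
            ratios.append(S[2] / floor)
        # s3 concentrates near (but below ~2x) the simple bound
        assert 0.3 < np.median(ratios) < 2.0

    def test_reconstruct_k_validation(self):
        res = svd_decompose(two_exp_matrix())
        with pytest.raises(ValueError):
            reconstruct(res, 0)
        with pytest.raises(ValueError):
            reconstruct(res, len(res.S) + 1)

    def test_reconstruction_error_non_increasing_in_k(self):
        A = two_exp_matrix(snr=10, seed=3)
        res = svd_decompose(A)
        errs = [np.sqrt(np.mean((reconstruct(res, k).dA - A.dA) ** 2))
                for k in range(1, len(res.S) + 1)]
        assert np.all(np.diff(errs) <= 1e-12)

    def test_rank2_denoising_beats_noise(self):
        sd = 1e-3
        A0 = two_exp_matrix(n_wl=24)
        rng = np.random.default_rng(8)
        A = SpectraMatrix(A0.wavelengths, A0.times, A0.dA + rng.normal(0, sd, A0.dA.shape))
        rec = reconstruct(svd_decompose(A), 2)
        resid = rec.dA - A.dA
        assert np.sqrt(np.mean(resid**2)) < sd


class TestSelectRank:
    def test_noiseless_rank_two(self):
        S = svd_decompose(two_exp_matrix()).S
        assert select_rank(S, 6, 60, noise_estimate=1e-9) == 2

    def test_all_noise_returns_zero_with_warning(self):
        rng = np.random.default_rng(4)
        S = np.linalg.svd(rng.normal(0, 1e-3, (20, 30)), compute_uv=False)
        with pytest.warns(UserWarning, match="noise floor"):
            assert select_rank(S, 20, 30, noise_estimate=1e-3) == 0

    def test_photocycle_rank_matches_spectral_overlap(self):
        """The default photocycle has P1 and P3 spectrally identical, so its
        noiseless matrix is rank 2; making P3 distinct raises it to 3."""
        from kinemap.synthetic_data import DEFAULT_PHOTOCYCLE, PhotocycleModel, Species, \
            simulate_photocycle_spectra

        times = np.geomspace(1e-6, 0.1, 50)
        wl = np.arange(340.0, 621.0, 5.0)
        A2 = simulate_photocycle_spectra(DEFAULT_PHOTOCYCLE, times, wl)
        assert select_rank(svd_decompose(A2).S, *A2.dA.shape, noise_estimate=1e-9) == 2
        distinct = PhotocycleModel(
            ground=DEFAULT_PHOTOCYCLE.ground, p1=DEFAULT_PHOTOCYCLE.p1,
            p2=DEFAULT_PHOTOCYCLE.p2,
            p3=Species("P3", 540.0, 35.0, 1.1),
            k2=DEFAULT_PHOTOCYCLE.k2, k3=DEFAULT_PHOTOCYCLE.k3, phi=0.3)
        A3 = simulate_photocycle_spectra(distinct, times, wl)
        assert select_rank(svd_decompose(A3).S, *A3.dA.shape, noise_estimate=1e-9) == 3


class TestGlobalFit:
    def test_zero_matrix(self):
        A = SpectraMatrix(wavelengths=np.arange(3.0), times=np.geomspace(1e-6, 1e-3, 20),
                          dA=np.zeros((3, 20)))
        fit = global_exp_fit(A, n_exp=2)
        assert np.allclose(fit.das, 0.0)
        assert fit.rms_residual == 0.0

    def test_single_exponential_exact(self):
        times = np.geomspace(1e-6, 10e-3, 60)
        dA = np.outer([1.0, -0.5], np.exp(-times / 1e-3))
        A = SpectraMatrix(wavelengths=np.array([400.0, 500.0]), times=times, dA=dA)
        fit = global_exp_fit(A, n_exp=1, offset=False)
        assert fit.tau[0] == pytest.approx(1e-3, rel=1e-3)
        assert fit.das[0] == pytest.approx([1.0, -0.5], rel=1e-6)

    def test_two_exponentials_with_noise(self):
        """tau = 10 us and 1 ms at SNR 100 both recovered within 5%."""
        for seed in range(3):
            A = two_exp_matrix(snr=100, seed=seed)
            fit = global_exp_fit(A, n_exp=2, offset=False)
            assert fit.tau[0] == pytest.approx(10e-6, rel=0.05)
            assert fit.tau[1] == pytest.approx(1e-3, rel=0.05)

    def test_varpro_agrees_with_full_nonlinear_fit(self):
        """Independent oracle: all parameters free in one nonlinear solve."""
        A = two_exp_matrix()
        fit = global_exp_fit(A, n_exp=2, offset=False)
        n_wl = len(A.wavelengths)

        def resid(p):
            t1, t2 = np.exp(p[:2])
            B = p[2:].reshape(2, n_wl)
            model = B[0][:, None] * np.exp(-A.times[None, :] / t1) \
                + B[1][:, None] * np.exp(-A.times[None, :] / t2)
            return (model - A.dA).ravel()

        x0 = np.concatenate([np.log([5e-6, 5e-4]), np.ones(2 * n_wl)])
        sol = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15)
        full_taus = np.sort(np.exp(sol.x[:2]))
        assert np.allclose(fit.tau, full_taus, rtol=1e-3)

    def test_model_reconstruction_shape_and_quality(self):
        A = two_exp_matrix()
        fit = global_exp_fit(A, n_exp=2, offset=False)
        model = fit.model(A.times)
        assert model.shape == A.dA.shape
        assert np.max(np.abs(model - A.dA)) < 1e-6 * np.max(np.abs(A.dA))

    def test_underfitting_raises_residual(self):
        A = two_exp_matrix()
        f2 = global_exp_fit(A, n_exp=2, offset=False)
        f1 = global_exp_fit(A, n_exp=1, offset=False)
        assert f2.rms_residual < f1.rms_residual


class TestSingleTrace:
    def test_constant_trace_goes_to_offset(self):
        times = np.geomspace(1e-6, 1e-2, 40)
        fit = fit_single_trace(times, np.full(40, 2.5), n_exp=1, offset=True)
        assert np.allclose(fit.das, 0.0, atol=1e-8)
        assert fit.offset[0] == pytest.approx(2.5)

    def test_recovery_200us(self):
        times = np.geomspace(1e-6, 10e-3, 80)
        y = 3.0 * np.exp(-times / 200e-6)
        fit = fit_single_trace(times, y, n_exp=1, offset=False)
        assert fit.tau[0] == pytest.approx(200e-6, rel=0.01)

    def test_consistent_with_matrix_form(self):
        times = np.geomspace(1e-6, 10e-3, 50)
        y = np.exp(-times / 1e-4) - 0.5 * np.exp(-times / 2e-3)
        single = fit_single_trace(times, y, n_exp=2, offset=False)
        A = SpectraMatrix(wavelengths=np.array([0.0]), times=times, dA=y[None, :])
        matrix = global_exp_fit(A, n_exp=2, offset=False)
        assert np.allclose(single.tau, matrix.tau, rtol=1e-10)


class TestCsvIO:
    def test_round_trip(self, tmp_path):
        A = two_exp_matrix(snr=50, seed=9)
        path = str(tmp_path / "dA.csv")
        write_spectra_csv(A, path)
        back = read_spectra_csv(path)
        assert np.allclose(back.wavelengths, A.wavelengths)
        assert np.allclose(back.times, A.times)
        assert np.allclose(back.dA, A.dA, atol=1e-12)
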