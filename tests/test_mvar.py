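"""MVAR estimation, PDC spectra, order selection and surrogate thresholds."""

import numpy as np
import pytest

from connfuse import (
    ChannelMontage, EpochSet, MVARGroundTruth, MVARModel, NumericalError,
    PDCMatrix, SurrogateNull, ValidationError, apply_threshold,
    band_average_pdc, ensemble_covariance, fit_mvar, matrix_from_directed,
    pdc, phase_randomize, select_order_bic, simulate_mvar_trials,
    surrogate_threshold, transfer_matrix, vectorize_directed,
)
from connfuse.experiments import analytic_var1_covariances


def _model(coeffs, fs=256.0, noise=None):
    coeffs = np.asarray(coeffs, dtype=float)
    n = coeffs.shape[1]
    return MVARModel(order=coeffs.shape[0], coeffs=coeffs,
                     noise_cov=noise if noise is not None else np.eye(n),
                     fs=fs, montage=ChannelMontage(tuple(f"c{i}" for i in range(n))))


class TestEnsembleCovariance:
    def test_single_trial_equals_its_own_covariance(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((2, 200, 1))
        ep = EpochSet(data=data, fs=256.0, onset_index=0,
                      montage=ChannelMontage(("a", "b")))
        covs = ensemble_covariance(ep, (0.0, 200 / 256.0), max_lag=2)
        x = data[:, :, 0] - data[:, :, 0].mean(axis=1, keepdims=True)
        manual = x[:, :-1] @ x[:, 1:].T / (200 - 1)
        assert np.allclose(covs.covariances[1], manual)

    def test_white_noise_covariances(self):
        model = MVARGroundTruth(order=1, coeffs=np.zeros((1, 3, 3)),
                                noise_cov=np.eye(3), fs=256.0)
        ep = simulate_mvar_trials(model, n_trials=250, n_samples=400,
                                  onset_index=0, seed=5)
        covs = ensemble_covariance(ep, (0.0, 400 / 256.0), max_lag=3)
        assert np.abs(covs.covariances[0] - np.eye(3)).max() < 0.05
        for m in (1, 2, 3):
            assert np.abs(covs.covariances[m]).max() < 0.05

    def test_window_too_short_rejected(self, ar3_epochs):
        with pytest.raises(ValidationError):
            ensemble_covariance(ar3_epochs, (0.0, 10 / 256.0), max_lag=15)


class TestFitMvar:
    def test_analytic_var1_oracle(self):
        # exact lag covariances -> exact coefficient recovery
        a = np.array([[0.5, 0.1], [0.2, 0.3]])
        covs = analytic_var1_covariances(a, np.eye(2), max_lag=3)
        model = fit_mvar(covs, 1)
        assert np.abs(model.coeffs[0] - a).max() < 1e-6
        # innovation covariance recovered too
        assert np.abs(model.noise_cov - np.eye(2)).max() < 1e-10

    def test_simulated_order2_recovery(self, ar3_truth):
        ep = simulate_mvar_trials(ar3_truth, n_trials=100, n_samples=500,
                                  onset_index=0, seed=21)
        covs = ensemble_covariance(ep, (0.0, 500 / 256.0), max_lag=4)
        model = fit_mvar(covs, 2)
        assert np.abs(model.coeffs - ar3_truth.coeffs).max() < 0.05

    def test_white_noise_gives_near_zero_coefficients(self):
        model = MVARGroundTruth(order=1, coeffs=np.zeros((1, 2, 2)),
                                noise_cov=np.eye(2), fs=256.0)
        ep = simulate_mvar_trials(model, n_trials=150, n_samples=400,
                                  onset_index=0, seed=6)
        covs = ensemble_covariance(ep, (0.0, 400 / 256.0), max_lag=2)
        fitted = fit_mvar(covs, 1)
        se = 1.0 / np.sqrt(150 * 400)
        assert np.abs(fitted.coeffs).max() < 3 * se * 5

    def test_singular_system_raises_numerical_error(self):
        from connfuse.mvar import LagCovarianceSet

        covs = LagCovarianceSet(
            covariances=np.zeros((3, 2, 2)), n_trials_used=1,
            n_window_samples=10, fs=256.0, montage=ChannelMontage(("a", "b")))
        with pytest.raises(NumericalError, match="condition"):
            fit_mvar(covs, 2)


class TestOrderSelection:
    def test_single_candidate_returned(self, ar3_epochs):
        assert select_order_bic(ar3_epochs, (0.0, 400 / 256.0), (5, 5)) == 5

    def test_true_order_recovered(self, ar3_epochs):
        assert select_order_bic(ar3_epochs, (0.0, 400 / 256.0), (1, 5)) == 2

    def test_white_noise_prefers_smallest(self):
        model = MVARGroundTruth(order=1, coeffs=np.zeros((1, 2, 2)),
                                noise_cov=np.eye(2), fs=256.0)
        hits = 0
        for seed in range(10):
            ep = simulate_mvar_trials(model, 30, 300, 0, seed=seed)
            hits += select_order_bic(ep, (0.0, 300 / 256.0), (1, 4)) == 1
        assert hits >= 9

    def test_empty_range_rejected(self, ar3_epochs):
        with pytest.raises(ValidationError):
            select_order_bic(ar3_epochs, (0.0, 1.0), (3, 2))


class TestTransferMatrixAndPdc:
    def test_zero_coefficients_identity(self):
        m = _model(np.zeros((1, 3, 3)))
        for f in (0.0, 10.0, 100.0):
            assert np.allclose(transfer_matrix(m, f), np.eye(3))
            assert np.allclose(pdc(m, f), np.eye(3))

    def test_dc_transfer_is_real(self):
        m = _model([[[0.5, 0.2], [0.1, 0.3]]])
        a = transfer_matrix(m, 0.0)
        assert np.allclose(a.imag, 0)
        assert np.allclose(a.real, np.eye(2) - m.coeffs[0])

    def test_quarter_sampling_rate_phase(self):
        m = _model([[[0.5]]])
        a = transfer_matrix(m, 64.0)  # fs/4 -> exp(-i pi/2) = -i
        assert np.isclose(a[0, 0], 1 + 0.5j)

    def test_bivariate_hand_example(self):
        m = _model([[[0.5, 0.0], [0.3, 0.5]]])
        p = pdc(m, 0.0)
        assert np.isclose(p[1, 0], 0.3 / np.sqrt(0.34), atol=1e-12)
        assert p[0, 1] == 0.0

    def test_column_normalization_invariant(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            coeffs = rng.normal(0, 0.2, (3, 4, 4))
            m = _model(coeffs)
            for f in rng.uniform(0, 120, 6):
                col_sq = np.sum(pdc(m, f) ** 2, axis=0)
                assert np.abs(col_sq - 1).max() < 1e-10


class TestBandAveragePdc:
    def test_flat_model_band_average_is_identity(self):
        m = _model(np.zeros((1, 3, 3)))
        assert np.allclose(band_average_pdc(m).values, np.eye(3))

    def test_single_frequency_band(self):
        m = _model([[[0.5, 0.0], [0.3, 0.5]]])
        single = band_average_pdc(m, band=(5.0, 5.0))
        assert np.allclose(single.values, pdc(m, 5.0))

    def test_planted_direction_dominates(self):
        truth = MVARGroundTruth(
            order=1, coeffs=np.array([[[0.5, 0.0], [0.3, 0.5]]]),
            noise_cov=np.eye(2), fs=256.0)
        ep = simulate_mvar_trials(truth, 48, 400, 0, seed=13)
        covs = ensemble_covariance(ep, (0.0, 400 / 256.0), max_lag=2)
        est = band_average_pdc(fit_mvar(covs, 1))
        assert est.values[1, 0] > est.values[0, 1]

    def test_direction_recovery_rate(self):
        # j -> i coupling of 0.3 at 48 trials recovered in nearly all runs
        truth = MVARGroundTruth(
            order=1, coeffs=np.array([[[0.5, 0.0], [0.3, 0.5]]]),
            noise_cov=np.eye(2), fs=256.0)
        hits = 0
        for seed in range(20):
            ep = simulate_mvar_trials(truth, 48, 384, 0, seed=100 + seed)
            covs = ensemble_covariance(ep, (0.0, 1.5), max_lag=2)
            est = band_average_pdc(fit_mvar(covs, 1))
            hits += est.values[1, 0] > est.values[0, 1]
        assert hits >= 19


class TestSurrogates:
    def test_amplitude_spectrum_preserved(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((2, 128, 3))
        surr = phase_randomize(data, np.random.default_rng(1))
        assert np.allclose(np.abs(np.fft.rfft(surr, axis=1)),
                           np.abs(np.fft.rfft(data, axis=1)), atol=1e-8)
        assert not np.allclose(surr, data)

    def test_planted_edge_exceeds_threshold(self):
        truth = MVARGroundTruth(
            order=1, coeffs=np.array([[[0.5, 0.0], [0.4, 0.5]]]),
            noise_cov=np.eye(2), fs=256.0)
        ep = simulate_mvar_trials(truth, 48, 768, 384, seed=14)
        covs = ensemble_covariance(ep, (0.1, 0.6), max_lag=2)
        observed = band_average_pdc(fit_mvar(covs, 1))
        null = surrogate_threshold(ep, p=1, n_surrogates=100, seed=2)
        assert observed.values[1, 0] > null.thresholds[1, 0]

    def test_null_edge_pass_rate_calibrates(self):
        # independent channels: each edge exceeds its alpha-threshold with
        # probability ~ alpha; pooled over datasets and edges
        model = MVARGroundTruth(order=1, coeffs=np.zeros((1, 3, 3)),
                                noise_cov=np.eye(3), fs=256.0)
        alpha = 0.1
        exceed, total = 0, 0
        for seed in range(15):
            ep = simulate_mvar_trials(model, 24, 512, 256, seed=200 + seed)
            covs = ensemble_covariance(ep, (0.1, 0.6), max_lag=2)
            observed = band_average_pdc(fit_mvar(covs, 2))
            null = surrogate_threshold(ep, p=2, n_surrogates=120,
                                       alpha=alpha, seed=seed)
            off = ~np.eye(3, dtype=bool)
            exceed += int(np.sum(observed.values[off] > null.thresholds[off]))
            total += int(off.sum())
        rate = exceed / total
        ci = 1.96 * np.sqrt(alpha * (1 - alpha) / total)
        assert abs(rate - alpha) < ci + 0.02

    def test_apply_threshold_elementwise(self):
        montage = ChannelMontage(("a", "b"))
        pdcm = PDCMatrix(values=np.array([[0.0, 0.6], [0.2, 0.0]]),
                         band=(4, 7), montage=montage)
        null = SurrogateNull(
            distributions=np.zeros((1, 2, 2)),
            thresholds=np.array([[0.0, 0.5], [0.5, 0.0]]),
            n_surrogates=100, alpha=0.05, montage=montage)
        out = apply_threshold(pdcm, null)
        assert out.values[0, 1] == 0.6  # above threshold survives
        assert out.values[1, 0] == 0.0  # below threshold zeroed
        assert out.thresholded


class TestVectorizeDirected:
    def _matrix(self, n):
        rng = np.random.default_rng(n)
        v = rng.uniform(0, 1, (n, n))
        np.fill_diagonal(v, 0)
        return PDCMatrix(values=v, band=(4, 7),
                         montage=ChannelMontage(tuple(f"c{i}" for i in range(n))))

    def test_twenty_channels_give_380_features(self):
        assert len(vectorize_directed(self._matrix(20))) == 380

    def test_three_channels_give_six(self):
        assert len(vectorize_directed(self._matrix(3))) == 6

    def test_reconstruction_inverts(self):
        m = self._matrix(5)
        back = matrix_from_directed(vectorize_directed(m), m.montage)
        assert np.allclose(back.values, m.values)

    def test_descriptor_direction_convention(self):
        m = self._matrix(3)
        feats = dict(vectorize_directed(m))
        # influence c1 -> c0 lives at matrix entry [0, 1]
        assert feats[("PDC", "c1", "c0")] == m.values[0, 1]
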