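"""Trial-ensemble MVAR estimation and partial directed coherence (PDC).

The multichannel signal is modelled as a multivariate autoregression

    X(n) = sum_{r=1..p} A_r X(n - r) + W(n),

fitted from trial-averaged lag covariances: each trial's windowed,
mean-centred covariance sequence R_n(m) is averaged over trials and the
multivariate Yule-Walker system is solved for the A_r by a block-
Toeplitz linear solve.  The directed spectral measure is the
column-normalized PDC

    PDC(i, j, f) = |Abar_ij(f)| / sqrt(sum_k |Abar_kj(f)|^2),

with Abar(f) = I - sum_r A_r exp(-i 2 pi f r / fs), so each column's
squared entries sum to one; entry (i, j) quantifies the influence of
channel j on channel i at frequency f.  Edge significance is assessed
against phase-randomized surrogates that preserve every channel's
amplitude spectrum while destroying cross-channel phase relations.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np

from ._exceptions import NumericalError, ValidationError
from .epochs import ChannelMontage, EpochSet
from .synthetic import companion_matrix

#: Descriptor tag used for directed features.
PDC_TAG = "PDC"


@dataclass
class MVARModel:
    """Estimated MVAR model (see module docstring for conventions)."""

    order: int
    coeffs: np.ndarray  # p x N x N
    noise_cov: np.ndarray
    fs: float
    montage: ChannelMontage

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        n = len(self.montage)
        if self.coeffs.shape != (self.order, n, n):
            raise ValidationError(
                f"coeffs must be {self.order} x {n} x {n}, got {self.coeffs.shape}"
            )
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-8):
            raise ValidationError("noise covariance must be symmetric (1e-8)")
        radius = np.abs(np.linalg.eigvals(companion_matrix(self.coeffs))).max()
        if radius >= 1.0:
            warn(
                f"estimated MVAR model is marginally unstable "
                f"(spectral radius {radius:.4f})",
                RuntimeWarning,
                stacklevel=2,
            )

    @property
    def n_channels(self) -> int:
        return len(self.montage)


@dataclass
class LagCovarianceSet:
    """Trial-averaged lag covariances Rbar(m), m = 0..max_lag.

    ``covariances[m]`` estimates E[X(n) X(n+m)^T]; negative lags follow
    from R(-m) = R(m)^T.
    """

    covariances: np.ndarray  # (max_lag + 1) x N x N
    n_trials_used: int
    n_window_samples: int
    fs: float
    montage: ChannelMontage

    @property
    def max_lag(self) -> int:
        return self.covariances.shape[0] - 1

    @property
    def n_effective(self) -> int:
        """Total windowed samples across trials (BIC sample size)."""
        return self.n_trials_used * self.n_window_samples


def ensemble_covariance(
    epochs: EpochSet,
    window: tuple[float, float] = (0.1, 0.6),
    max_lag: int = 9,
) -> LagCovarianceSet:
    """Per-trial windowed lag covariances, averaged over trials.

    Each trial's window is mean-centred per channel; lag-m covariance is
    the average of x(t) x(t+m)^T over the L - m contributing pairs
    (unbiased per lag).
    """
    tidx = epochs.window_indices(window)
    L = tidx.size
    if L <= max_lag + 1:
        raise ValidationError(
            f"window holds {L} samples, need more than max_lag + 1 = {max_lag + 1}"
        )
    x = epochs.data[:, tidx, :]  # N x L x T
    x = x - x.mean(axis=1, keepdims=True)
    n = epochs.n_channels
    covs = np.empty((max_lag + 1, n, n))
    for m in range(max_lag + 1):
        # mean over trials of mean over pairs of x(t) x(t+m)^T
        head = x[:, : L - m, :]
        tail = x[:, m:, :]
        covs[m] = np.einsum("ilt,jlt->ij", head, tail) / ((L - m) * epochs.n_trials)
    return LagCovarianceSet(
        covariances=covs, n_trials_used=epochs.n_trials,
        n_window_samples=L, fs=epochs.fs, montage=epochs.montage,
    )


def fit_mvar(covs: LagCovarianceSet, p: int) -> MVARModel:
    """Solve the multivariate Yule-Walker equations for order ``p``.

    With C(k) = E[X(n) X(n-k)^T] = R(k)^T the normal equations are
    C(k) = sum_r A_r C(k - r) for k = 1..p; stacked over k they form a
    block-Toeplitz linear system solved directly.  The innovation
    covariance is R(0) - sum_r A_r R(r), symmetrized.
    """
    if p < 1:
        raise ValidationError("order must be >= 1")
    if covs.max_lag < p:
        raise ValidationError(f"need lag covariances up to {p}, have {covs.max_lag}")
    r = covs.covariances
    n = r.shape[1]

    def c(k: int) -> np.ndarray:  # C(k) = R(k)^T; C(-k) = C(k)^T = R(k)
        return r[k].T if k >= 0 else r[-k]

    # [A_1 ... A_p] @ T = [C(1) ... C(p)],  T[r, k] block = C(k - r)
    big = np.empty((p * n, p * n))
    rhs = np.empty((n, p * n))
    for col in range(p):
        rhs[:, col * n:(col + 1) * n] = c(col + 1)
        for row in range(p):
            big[row * n:(row + 1) * n, col * n:(col + 1) * n] = c(col - row)
    cond = np.linalg.cond(big)
    if not np.isfinite(cond) or cond > 1e12:
        raise NumericalError(
            f"Yule-Walker system is ill-conditioned (condition estimate {cond:.3e})"
        )
    stacked = np.linalg.solve(big.T, rhs.T).T  # N x pN
    coeffs = np.stack([stacked[:, k * n:(k + 1) * n] for k in range(p)])
    sigma = r[0].copy()
    for k in range(1, p + 1):
        sigma -= coeffs[k - 1] @ r[k]
    sigma = 0.5 * (sigma + sigma.T)
    return MVARModel(order=p, coeffs=coeffs, noise_cov=sigma,
                     fs=covs.fs, montage=covs.montage)


def select_order_bic(
    epochs: EpochSet,
    window: tuple[float, float] = (0.1, 0.6),
    p_range: tuple[int, int] = (1, 15),
) -> int:
    """Pick the MVAR order minimizing a Bayesian information criterion.

    BIC(p) = ln det(Sigma_p) + p N^2 ln(n_eff) / n_eff, where n_eff is
    the total number of windowed samples across trials.  Ties go to the
    smallest order.
    """
    p_lo, p_hi = p_range
    if p_hi < p_lo or p_lo < 1:
        raise ValidationError(f"invalid order range {p_range}")
    covs = ensemble_covariance(epochs, window, max_lag=p_hi)
    n_eff = covs.n_effective
    best_p, best_bic = None, np.inf
    for p in range(p_lo, p_hi + 1):
        model = fit_mvar(covs, p)
        sign, logdet = np.linalg.slogdet(model.noise_cov)
        if sign <= 0:
            continue  # covariance collapsed; over-parameterized candidate
        bic = logdet + p * model.n_channels**2 * np.log(n_eff) / n_eff
        if bic < best_bic - 1e-12:
            best_p, best_bic = p, bic
    if best_p is None:
        raise NumericalError("no candidate order gave a positive-definite fit")
    return best_p


def transfer_matrix(model: MVARModel, f: float) -> np.ndarray:
    """Abar(f) = I - sum_r A_r exp(-i 2 pi f r / fs)."""
    if not (0 <= f < model.fs / 2):
        raise ValidationError(f"frequency {f} outside [0, Nyquist)")
    n = model.n_channels
    phases = np.exp(-2j * np.pi * f * np.arange(1, model.order + 1) / model.fs)
    return np.eye(n, dtype=complex) - np.tensordot(phases, model.coeffs, axes=(0, 0))


def pdc(model: MVARModel, f: float) -> np.ndarray:
    """Column-normalized PDC at one frequency; columns' squares sum to 1."""
    a = transfer_matrix(model, f)
    col_norm = np.sqrt(np.sum(np.abs(a) ** 2, axis=0))
    if np.any(col_norm == 0):
        raise NumericalError("zero column norm in transfer matrix")
    return np.abs(a) / col_norm[np.newaxis, :]


@dataclass
class PDCMatrix:
    """Directed connectivity, band-averaged: values[i, j] = influence j -> i."""

    values: np.ndarray
    band: tuple[float, float]
    montage: ChannelMontage
    thresholded: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.montage)
        if v.shape != (n, n):
            raise ValidationError(f"values must be {n} x {n}")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValidationError("PDC values must lie in [0, 1]")
        self.values = v


def band_average_pdc(
    model: MVARModel,
    band: tuple[float, float] = (4.0, 7.0),
    freq_step: float = 0.25,
) -> PDCMatrix:
    """Arithmetic mean of PDC over the grid f_lo, f_lo+step, ..., f_hi."""
    f_lo, f_hi = band
    if f_hi >= model.fs / 2:
        raise ValidationError("band upper edge reaches Nyquist")
    grid = np.arange(f_lo, f_hi + freq_step / 2, freq_step)
    grid = grid[grid <= f_hi + 1e-12]
    if grid.size == 0:
        raise ValidationError(f"empty frequency grid for band {band}")
    mean = np.mean([pdc(model, f) for f in grid], axis=0)
    return PDCMatrix(values=mean, band=band, montage=model.montage)


@dataclass
class SurrogateNull:
    """Per-edge null distribution of band-averaged PDC under surrogates."""

    distributions: np.ndarray  # n_surrogates x N x N
    thresholds: np.ndarray  # N x N, (1 - alpha) empirical quantile
    n_surrogates: int
    alpha: float
    montage: ChannelMontage


def phase_randomize(data: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fourier phase-randomized copy of ``channels x samples x trials``.

    Each channel and trial receives independent uniform phases; Hermitian
    symmetry is preserved (DC and Nyquist bins stay real), so amplitude
    spectra are untouched and the inverse transform is real.
    """
    n_ch, n_samp, n_tr = data.shape
    spec = np.fft.rfft(data, axis=1)
    n_bins = spec.shape[1]
    # bins 1..last interior bin get random phases; keep DC (and Nyquist
    # when n_samp is even) real
    interior = slice(1, n_bins - 1 if n_samp % 2 == 0 else n_bins)
    k = spec[:, interior, :].shape[1]
    phases = rng.uniform(0.0, 2 * np.pi, size=(n_ch, k, n_tr))
    spec[:, interior, :] = np.abs(spec[:, interior, :]) * np.exp(1j * phases)
    return np.fft.irfft(spec, n=n_samp, axis=1)


def surrogate_threshold(
    epochs: EpochSet,
    window: tuple[float, float] = (0.1, 0.6),
    band: tuple[float, float] = (4.0, 7.0),
    p: int = 9,
    n_surrogates: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    freq_step: float = 0.25,
) -> SurrogateNull:
    """Empirical per-edge PDC null from phase-randomized surrogates.

    Every surrogate randomizes each channel's and trial's Fourier
    phases, refits the MVAR model and recomputes the band-averaged PDC;
    edge thresholds are the (1 - alpha) quantiles.
    """
    if n_surrogates < 100:
        raise ValidationError("n_surrogates must be >= 100")
    rng = np.random.default_rng(seed)
    n = epochs.n_channels
    dists = np.empty((n_surrogates, n, n))
    for s in range(n_surrogates):
        surr = EpochSet(
            data=phase_randomize(epochs.data, rng), fs=epochs.fs,
            onset_index=epochs.onset_index, montage=epochs.montage,
            subject_id=epochs.subject_id, group=epochs.group,
        )
        covs = ensemble_covariance(surr, window, max_lag=p)
        model = fit_mvar(covs, p)
        dists[s] = band_average_pdc(model, band, freq_step).values
    thresholds = np.quantile(dists, 1.0 - alpha, axis=0)
    return SurrogateNull(
        distributions=dists, thresholds=thresholds,
        n_surrogates=n_surrogates, alpha=alpha, montage=epochs.montage,
    )


def apply_threshold(pdcm: PDCMatrix, null: SurrogateNull) -> PDCMatrix:
    """Zero every edge at or below its surrogate threshold."""
    if null.montage.labels != pdcm.montage.labels:
        raise ValidationError("surrogate null and PDC matrix montages differ")
    vals = np.where(pdcm.values > null.thresholds, pdcm.values, 0.0)
    return PDCMatrix(values=vals, band=pdcm.band, montage=pdcm.montage,
                     thresholded=True)


def vectorize_directed(matrix: PDCMatrix) -> list[tuple[tuple[str, str, str], float]]:
    """All ordered off-diagonal pairs, row-major, as (descriptor, value).

    Descriptors are ``(PDC_TAG, source, target)`` (value at matrix entry
    [target, source]); a 20-channel matrix yields 380 features.
    """
    labels = matrix.montage.labels
    n = len(labels)
    return [
        ((PDC_TAG, labels[j], labels[i]), float(matrix.values[i, j]))
        for i in range(n)
        for j in range(n)
        if i != j
    ]


def matrix_from_directed(
    features: list[tuple[tuple[str, str, str], float]],
    montage: ChannelMontage,
    band: tuple[float, float] = (4.0, 7.0),
    thresholded: bool = False,
) -> PDCMatrix:
    """Rebuild a directed matrix (zero diagonal) from its vectorization."""
    n = len(montage)
    vals = np.zeros((n, n))
    for (tag, src, tgt), v in features:
        if tag != PDC_TAG:
            raise ValidationError(f"not a directed feature descriptor: {tag}")
        vals[montage.index(tgt), montage.index(src)] = v
    return PDCMatrix(values=vals, band=band, montage=montage,
                     thresholded=thresholded)
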