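"""Phase lag index (PLI) functional connectivity.

For a channel pair the PLI at a time-frequency point is the absolute
mean over trials of the sign of the instantaneous phase difference,

    PLI(f, t) = | (1/M) * sum_m sgn(dphi_m(f, t)) |,

with sgn(0) = 0.  Zero-lag (volume-conducted) coupling produces phase
differences symmetric around zero and is therefore discounted.  Band-
and window-averaged values form a symmetric channel x channel matrix
with zero diagonal; phase differences come from the same Morlet
coefficients as the power analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import ValidationError
from .epochs import ChannelMontage, EpochSet
from .timefreq import TFCoefficients, WaveletBank, morlet_transform

#: Descriptor tag used for undirected features.
PLI_TAG = "PLI"


@dataclass
class PLIMatrix:
    """Symmetric channel x channel PLI, averaged over a band and window."""

    values: np.ndarray
    band: tuple[float, float]
    window: tuple[float, float]
    montage: ChannelMontage

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.montage)
        if v.shape != (n, n):
            raise ValidationError(f"values must be {n} x {n}")
        if not np.array_equal(v, v.T):
            raise ValidationError("PLI matrix must be exactly symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("PLI diagonal must be exactly zero")
        if v.min() < 0 or v.max() > 1:
            raise ValidationError("PLI values must lie in [0, 1]")
        self.values = v


def pli_timefreq(coeffs_a: TFCoefficients | np.ndarray,
                 coeffs_b: TFCoefficients | np.ndarray) -> np.ndarray:
    """PLI per time-frequency point from two channels' complex coefficients.

    Accepts two single-channel coefficient sets (freqs x samples x
    trials after squeezing) and returns a freqs x samples array.
    """

    def _vals(c):
        if isinstance(c, TFCoefficients):
            if c.values.shape[0] != 1:
                raise ValidationError("pli_timefreq expects single-channel inputs")
            return c.values[0]
        return np.asarray(c)

    a, b = _vals(coeffs_a), _vals(coeffs_b)
    if a.shape != b.shape:
        raise ValidationError(
            f"coefficient shapes differ: {a.shape} vs {b.shape} "
            "(trial counts and grids must match)"
        )
    # sgn(dphi) = sgn(sin(dphi)) = sgn(Im[a conj(b)]) for dphi in (-pi, pi);
    # a relative tolerance keeps rounding noise of truly zero-lag pairs
    # (|Im| ~ 1e-16 |z| for identical inputs) in the sgn(0) = 0 branch.
    prod = a * np.conj(b)
    signs = np.sign(prod.imag)
    signs[np.abs(prod.imag) <= 1e-9 * np.abs(prod)] = 0.0
    return np.abs(np.mean(signs, axis=-1))


def pli_matrix(
    epochs: EpochSet,
    bank: WaveletBank,
    band: tuple[float, float] = (4.0, 7.0),
    window: tuple[float, float] = (0.1, 0.6),
) -> PLIMatrix:
    """Band- and window-averaged PLI for every channel pair.

    Bank frequencies with ``f_lo <= f <= f_hi`` (inclusive) and samples
    with ``t0 <= t < t1`` enter the average jointly.
    """
    fidx = bank.band_indices(band)
    sub_bank = WaveletBank(freqs=bank.freqs[fidx], cycles=bank.cycles[fidx],
                           fs=bank.fs)
    tidx = epochs.window_indices(window)
    coeffs = morlet_transform(epochs, sub_bank)
    vals = coeffs.values[:, :, tidx, :]  # channels x band freqs x win x trials
    n = epochs.n_channels
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            pli = pli_timefreq(vals[a], vals[b]).mean()
            out[a, b] = out[b, a] = pli
    return PLIMatrix(values=out, band=band, window=window, montage=epochs.montage)


def vectorize_upper(matrix: PLIMatrix) -> list[tuple[tuple[str, str, str], float]]:
    """Row-major upper triangle as ordered (descriptor, value) pairs.

    Descriptors are ``(PLI_TAG, channel_a, channel_b)`` with a before b
    in montage order; a 20-channel matrix yields 190 features.  The
    mapping is inverted by :func:`matrix_from_upper`.
    """
    labels = matrix.montage.labels
    n = len(labels)
    return [
        ((PLI_TAG, labels[a], labels[b]), float(matrix.values[a, b]))
        for a in range(n)
        for b in range(a + 1, n)
    ]


def matrix_from_upper(
    features: list[tuple[tuple[str, str, str], float]],
    montage: ChannelMontage,
    band: tuple[float, float] = (4.0, 7.0),
    window: tuple[float, float] = (0.1, 0.6),
) -> PLIMatrix:
    """Rebuild the symmetric matrix from its upper-triangle vectorization."""
    n = len(montage)
    vals = np.zeros((n, n))
    for (tag, la, lb), v in features:
        if tag != PLI_TAG:
            raise ValidationError(f"not an undirected feature descriptor: {tag}")
        a, b = montage.index(la), montage.index(lb)
        vals[a, b] = vals[b, a] = v
    return PLIMatrix(values=vals, band=band, window=window, montage=montage)
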