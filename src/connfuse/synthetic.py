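"""Two-group synthetic EEG studies with known connectivity ground truth.

Subjects are simulated as stationary multivariate autoregressive (MVAR)
trial ensembles.  Directed ground truth is planted by adding coefficient
deltas to specific edges of one group's MVAR model; undirected (phase
synchronization) ground truth is planted by superposing narrow-band
oscillator pairs whose phase lag is consistent across trials in one
group and uniformly random in the other.  Optional instantaneous mixing
emulates volume conduction.  Every generator is fully deterministic
given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ValidationError
from .epochs import ChannelMontage, EpochSet, DEFAULT_CHANNELS


@dataclass
class MVARGroundTruth:
    """A known MVAR process: X(n) = sum_r A_r X(n-r) + W(n).

    ``coeffs`` is lag-indexed ``p x N x N`` (entry [r-1, i, j] couples
    channel j at lag r into channel i); ``noise_cov`` is the innovation
    covariance of W.
    """

    order: int
    coeffs: np.ndarray
    noise_cov: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValidationError(
                f"coeffs must be p x N x N, got shape {self.coeffs.shape}"
            )
        if self.coeffs.shape[0] != self.order:
            raise ValidationError("coeffs first dimension must equal order")
        n = self.coeffs.shape[1]
        if self.noise_cov.shape != (n, n):
            raise ValidationError("noise_cov shape must match channel count")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-10):
            raise ValidationError("noise_cov must be symmetric")
        if np.linalg.eigvalsh(self.noise_cov).min() <= 0:
            raise ValidationError("noise_cov must be positive definite")

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Companion form of the lag-coefficient stack (pN x pN)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
        raise ValidationError("coefficient matrices must be square")
    p, n, _ = coeffs.shape
    comp = np.zeros((p * n, p * n))
    comp[:n] = coeffs.transpose(1, 0, 2).reshape(n, p * n)
    if p > 1:
        comp[n:, :-n] = np.eye((p - 1) * n)
    return comp


def is_stable(model: MVARGroundTruth | np.ndarray) -> bool:
    """True iff the companion-matrix spectral radius is below one."""
    coeffs = model.coeffs if isinstance(model, MVARGroundTruth) else model
    radius = np.abs(np.linalg.eigvals(companion_matrix(coeffs))).max()
    return bool(radius < 1.0)


def simulate_mvar_trials(
    model: MVARGroundTruth,
    n_trials: int,
    n_samples: int,
    onset_index: int,
    seed: int,
    montage: ChannelMontage | None = None,
    subject_id: str = "",
    group: str = "",
) -> EpochSet:
    """Independent stationary realizations of ``model``, one per trial.

    A burn-in of ``100 * order`` samples is generated and discarded per
    trial so the retained segment is (numerically) stationary.
    """
    if not is_stable(model):
        raise ValidationError("MVAR model is not stationary (spectral radius >= 1)")
    p, n = model.order, model.n_channels
    if n_samples <= 10 * max(p, 1):
        raise ValidationError("n_samples must exceed 10x the model order")
    burn = 100 * max(p, 1)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(model.noise_cov)
    total = burn + n_samples
    # innovations for all trials at once; recursion vectorized over trials
    z = rng.standard_normal((total, n, n_trials))
    w = np.einsum("ij,tjm->tim", chol, z)
    x = np.zeros((total, n, n_trials))
    for t in range(total):
        acc = w[t]
        for r in range(1, min(p, t) + 1):
            acc = acc + model.coeffs[r - 1] @ x[t - r]
        x[t] = acc
    data = np.ascontiguousarray(x[burn:].transpose(1, 0, 2))
    if montage is None:
        montage = ChannelMontage(tuple(f"ch{i}" for i in range(n)))
    return EpochSet(
        data=data, fs=model.fs, onset_index=onset_index, montage=montage,
        subject_id=subject_id, group=group,
    )


def simulate_lagged_oscillators(
    freq: float,
    lag: float,
    jitter_sd: float,
    n_trials: int,
    n_samples: int,
    fs: float,
    seed: int,
    onset_index: int = 0,
    amplitude: float = 1.0,
) -> EpochSet:
    """Two narrow-band channels with a trial-consistent phase lag.

    Channel b's phase equals channel a's phase plus ``lag`` plus a
    per-trial Gaussian jitter of SD ``jitter_sd`` radians.  Passing
    ``jitter_sd = inf`` draws the lag uniformly on (-pi, pi) each trial
    (no phase consistency).  Amplitude envelopes are independent slow
    random modulations around ``amplitude``.
    """
    if not (0 < freq < fs / 2):
        raise ValidationError(f"oscillator frequency {freq} must lie in (0, Nyquist)")
    if jitter_sd < 0:
        raise ValidationError("jitter_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    data = np.empty((2, n_samples, n_trials))
    for m in range(n_trials):
        phi0 = rng.uniform(-np.pi, np.pi)
        if np.isinf(jitter_sd):
            dphi = rng.uniform(-np.pi, np.pi)
        else:
            dphi = lag + rng.normal(0.0, jitter_sd)
        env_a = amplitude * (1.0 + 0.1 * rng.standard_normal())
        env_b = amplitude * (1.0 + 0.1 * rng.standard_normal())
        data[0, :, m] = env_a * np.cos(2 * np.pi * freq * t + phi0)
        data[1, :, m] = env_b * np.cos(2 * np.pi * freq * t + phi0 + dphi)
    return EpochSet(
        data=data, fs=fs, onset_index=onset_index,
        montage=ChannelMontage(("osc_a", "osc_b")),
    )


def apply_instantaneous_mixing(epochs: EpochSet, mixing: np.ndarray) -> EpochSet:
    """Replace every sample vector x by ``mixing @ x`` (volume conduction)."""
    mixing = np.asarray(mixing, dtype=float)
    n = epochs.n_channels
    if mixing.shape != (n, n):
        raise ValidationError(
            f"mixing must be {n} x {n}, got {mixing.shape}"
        )
    mixed = np.einsum("ij,jst->ist", mixing, epochs.data)
    out = EpochSet(
        data=mixed, fs=epochs.fs, onset_index=epochs.onset_index,
        montage=epochs.montage, subject_id=epochs.subject_id, group=epochs.group,
    )
    return out


def default_base_model(n_channels: int = 20, fs: float = 256.0,
                       osc_freq: float = 6.0, pole_radius: float = 0.65,
                       neighbor_coupling: float = 0.01) -> MVARGroundTruth:
    """A stable order-2 background model with theta-band resonances.

    Each channel is a damped oscillator (AR(2) poles at ``osc_freq`` Hz,
    radius ``pole_radius``), with weak nearest-neighbour coupling so the
    background is genuinely multivariate but carries no planted
    asymmetry.
    """
    a1 = 2 * pole_radius * np.cos(2 * np.pi * osc_freq / fs)
    a2 = -pole_radius**2
    coeffs = np.zeros((2, n_channels, n_channels))
    coeffs[0] += np.eye(n_channels) * a1
    coeffs[1] += np.eye(n_channels) * a2
    for i in range(n_channels - 1):
        coeffs[0, i, i + 1] = neighbor_coupling
        coeffs[0, i + 1, i] = neighbor_coupling
    model = MVARGroundTruth(order=2, coeffs=coeffs,
                            noise_cov=np.eye(n_channels), fs=fs)
    if not is_stable(model):  # pragma: no cover - defaults are stable
        raise ValidationError("default base model parameters are unstable")
    return model


@dataclass
class StudyConfig:
    """Conditions of one simulated two-group study.

    Defaults mirror the epoch geometry of negative-feedback ERP trials:
    48 trials per subject, 768 samples at 256 Hz spanning (-1.5, 1.5) s
    with onset at sample 384, and the 20-channel montage.
    """

    n_subjects_per_group: int = 20
    n_trials: int = 48
    n_samples: int = 768
    onset_index: int = 384
    fs: float = 256.0
    base_model: MVARGroundTruth | None = None
    #: (source_label, target_label, coefficient delta at lag 1), applied
    #: to the *effect* group only.
    group_effect_edges: list[tuple[str, str, float]] = field(default_factory=list)
    #: (label_a, label_b, freq Hz, lag radians, jitter SD radians,
    #:  group with the consistent lag).  The other group receives the
    #: same oscillator power with uniformly random per-trial lags.
    oscillator_pairs: list[tuple[str, str, float, float, float, str]] = field(
        default_factory=list
    )
    oscillator_amplitude: float = 1.5
    subject_jitter_sd: float = 0.005
    mixing: np.ndarray | None = None
    montage: ChannelMontage = field(
        default_factory=lambda: ChannelMontage(DEFAULT_CHANNELS)
    )
    groups: tuple[str, str] = ("SZ", "HC")
    effect_group: str = "SZ"
    seed: int = 0
    max_stationarity_retries: int = 20

    def __post_init__(self) -> None:
        if self.base_model is None:
            self.base_model = default_base_model(len(self.montage), self.fs)
        if self.n_subjects_per_group < 1:
            raise ValidationError("n_subjects_per_group must be >= 1")
        if self.base_model.n_channels != len(self.montage):
            raise ValidationError("base model channel count must match montage")
        for pair in self.oscillator_pairs:
            if pair[4] < 0:
                raise ValidationError("oscillator phase jitter SD must be >= 0")


def _subject_model(config: StudyConfig, group: str, rng: np.random.Generator
                   ) -> MVARGroundTruth:
    """Perturb the base model for one subject; retry until stationary."""
    base = config.base_model
    jitter = config.subject_jitter_sd
    for _ in range(config.max_stationarity_retries):
        coeffs = base.coeffs + rng.normal(0.0, jitter, size=base.coeffs.shape)
        if group == config.effect_group:
            for src, tgt, delta in config.group_effect_edges:
                i = config.montage.index(tgt)
                j = config.montage.index(src)
                coeffs[0, i, j] += delta
        if is_stable(coeffs):
            return MVARGroundTruth(order=base.order, coeffs=coeffs,
                                   noise_cov=base.noise_cov.copy(), fs=base.fs)
        jitter *= 0.5
    raise ValidationError(
        "could not generate a stationary subject model; reduce subject_jitter_sd "
        "or the group effect deltas"
    )


def simulate_subject(config: StudyConfig, group: str, subject_id: str,
                     seed: int) -> EpochSet:
    """One subject's EpochSet under ``config`` for the given group."""
    rng = np.random.default_rng(seed)
    model = _subject_model(config, group, rng)
    epochs = simulate_mvar_trials(
        model, config.n_trials, config.n_samples, config.onset_index,
        seed=int(rng.integers(2**31)), montage=config.montage,
        subject_id=subject_id, group=group,
    )
    data = epochs.data
    for (la, lb, freq, lag, jitter_sd, strong_group) in config.oscillator_pairs:
        eff_jitter = jitter_sd if group == strong_group else np.inf
        osc = simulate_lagged_oscillators(
            freq, lag, eff_jitter, config.n_trials, config.n_samples,
            config.fs, seed=int(rng.integers(2**31)),
            onset_index=config.onset_index, amplitude=config.oscillator_amplitude,
        )
        data[config.montage.index(la)] += osc.data[0]
        data[config.montage.index(lb)] += osc.data[1]
    epochs = EpochSet(data=data, fs=config.fs, onset_index=config.onset_index,
                      montage=config.montage, subject_id=subject_id, group=group)
    if config.mixing is not None:
        epochs = apply_instantaneous_mixing(epochs, config.mixing)
    return epochs


def simulate_two_group_study(config: StudyConfig) -> dict:
    """Simulate all subjects of a two-group study.

    Returns a manifest dictionary::

        {"subjects": [{"subject_id", "group", "epochs": EpochSet}, ...],
         "ground_truth": {"directed_edges": [...], "phase_pairs": [...]}}

    The ground truth names the edges that truly differ between groups;
    it is carried alongside the data and must never be handed to the
    estimators.
    """
    ss = np.random.SeedSequence(config.seed)
    n = config.n_subjects_per_group
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n)]
    subjects = []
    k = 0
    for group in config.groups:
        for i in range(n):
            sid = f"{group.lower()}{i:03d}"
            subjects.append({
                "subject_id": sid,
                "group": group,
                "epochs": simulate_subject(config, group, sid, child_seeds[k]),
            })
            k += 1
    ground_truth = {
        "directed_edges": [
            {"source": s, "target": t, "delta": d, "group": config.effect_group}
            for (s, t, d) in config.group_effect_edges
        ],
        "phase_pairs": [
            {"a": a, "b": b, "freq": f, "lag": lag, "jitter_sd": j,
             "consistent_group": g}
            for (a, b, f, lag, j, g) in config.oscillator_pairs
        ],
    }
    return {"subjects": subjects, "ground_truth": ground_truth}
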