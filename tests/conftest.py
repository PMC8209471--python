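import numpy as np
import pytest

from connfuse import (
    ChannelMontage, EpochSet, MVARGroundTruth, build_wavelet_bank,
    simulate_mvar_trials,
)


@pytest.fixture(scope="session")
def bank():
    """The default 50-point Morlet bank at 256 Hz."""
    return build_wavelet_bank()


@pytest.fixture
def small_epochs():
    """A small deterministic EpochSet (3 channels, 64 samples, 5 trials)."""
    rng = np.random.default_rng(42)
    return EpochSet(
        data=rng.standard_normal((3, 64, 5)),
        fs=256.0,
        onset_index=32,
        montage=ChannelMontage(("Fz", "Cz", "Pz")),
        subject_id="s000",
        group="HC",
    )


@pytest.fixture(scope="session")
def ar3_truth():
    """Stable 3-channel order-2 ground-truth model."""
    coeffs = np.array([
        [[0.50, 0.10, 0.00],
         [0.00, 0.40, 0.20],
         [0.15, 0.00, 0.30]],
        [[-0.20, 0.00, 0.00],
         [0.00, -0.10, 0.05],
         [0.00, 0.10, -0.15]],
    ])
    return MVARGroundTruth(order=2, coeffs=coeffs, noise_cov=np.eye(3), fs=256.0)


@pytest.fixture(scope="session")
def ar3_epochs(ar3_truth):
    return simulate_mvar_trials(ar3_truth, n_trials=60, n_samples=400,
                                onset_index=0, seed=101)
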