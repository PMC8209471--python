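# Methods

`connfuse` implements a complete analysis chain for discriminating two
subject groups from epoched, multi-trial EEG by fusing two kinds of
theta-band connectivity features: undirected phase synchronization
(phase lag index, PLI) and directed Granger-causal influence (partial
directed coherence, PDC), classified with a linear SVM under
leave-one-out cross-validation (LOOCV) and validated with permutation
statistics. This note records the models, conventions, parameter
choices and known limitations.

## Data model and time conventions

A subject is an `EpochSet`: a `channels x samples x trials` array with
sampling rate `fs`, an onset index, and an ordered channel montage
(default: 20 scalp electrodes of the 10-20 system). Sample `i` maps to
time `(i - onset_index)/fs` seconds, and every analysis window is
half-open, `t0 <= t < t1`. This convention is load-bearing: a
(-1.5, 1.5) s epoch at 256 Hz has 768 samples, the statistics window
[-0.2, 1.0) s contains exactly 307 samples (50 x 307 = 15,350 pixels),
the connectivity window [0.1, 0.6) s exactly 128, and the baseline
[-0.2, -0.1) s exactly 26. On disk an `EpochSet` is a UTF-8 JSON
metadata file plus a raw little-endian float64 payload in channel-major
order; round-trips are bit-exact. No vendor EEG formats are read: data
are assumed cleaned and epoched upstream.

## Time-frequency decomposition

Single-trial spectral estimates use complex Morlet wavelets (Gaussian-
windowed exponentials, temporal SD `cycles/(2*pi*f)`, unit energy,
same-length zero-padded convolution, computed with MNE's
`tfr_array_morlet`). The bank holds 50 centre frequencies linearly
spaced 3.9-40 Hz with cycle counts linearly spaced 3-11.4, so temporal
resolution tightens as frequency grows. Power maps average `|c|^2`
over trials and the selected channels, then express each frequency row
as `10*log10(power / baseline mean)` with baseline [-0.2, -0.1) s.
Edge-contaminated margins are excluded from statistics by restricting
tests to [-0.2, 1.0) s.

Group maps are compared with a cluster-based permutation test: pooled-
variance two-sample t per pixel, two-sided threshold at pixel alpha
0.01, 4-connected clusters scored by pixel count, and a null of largest
cluster sizes over random relabelings of the subjects (10,000 by
default). Observed clusters survive if their size strictly exceeds the
(1 - 0.05) percentile of the null. Cluster size (not summed t) is the
cluster statistic, and clusters are formed from both t signs jointly.
Internally the permutations are drawn over a content-canonical subject
ordering, which makes the result bit-identical under swapping the two
group lists.

## PLI

For channels a, b the phase lag index at a time-frequency point is
`|mean_m sgn(dphi_m)|` over trials, where `dphi` is the phase of
`c_a * conj(c_b)` from the same Morlet coefficients that feed the power
analysis. The sign is computed as `sgn(Im[c_a conj(c_b)])` — identical
to `sgn(dphi)` on (-pi, pi) — with a relative tolerance (1e-9) mapping
numerically-zero imaginary parts to the `sgn(0) = 0` branch; without
this, exactly zero-lag (volume-conducted) pairs would pick up rounding
noise of order 1e-16 and produce spurious +/-1 signs. Matrices average
jointly over bank frequencies inside the inclusive theta band
[4, 7] Hz and samples in [0.1, 0.6) s, giving a symmetric, zero-
diagonal 20 x 20 matrix whose 190 upper-triangle entries are features.
PLI is invariant to channel-wise amplitude scaling, symmetric in the
pair, and discounts instantaneous mixing (sign-symmetric phase
differences average out), which the tests verify against explicitly
mixed independent sources.

## MVAR and PDC

Each subject's windowed trials are modelled as a stationary MVAR
process `X(n) = sum_r A_r X(n-r) + W(n)`. Estimation follows the
trial-ensemble route: per trial, the [0.1, 0.6) s window is mean-
centred per channel and lag covariances `R(m)` are computed with an
unbiased per-lag divisor (the window is only 128 samples, so the
divisor choice is material); covariances are averaged over trials and
the multivariate Yule-Walker system `C(k) = sum_r A_r C(k-r)`
(`C(k) = R(k)^T`) is solved as one block-Toeplitz linear system, with a
condition-number guard (error above 1e12). The innovation covariance
is `R(0) - sum_r A_r R(r)`, symmetrized. A direct solve and the LWR
recursion agree on well-conditioned inputs; the direct solve was chosen
for transparency. The fit is verified to machine precision against
analytic VAR(1) covariances obtained from the discrete Lyapunov
equation — an oracle independent of the estimation path.

Model order can be fixed (the clinical analysis this emulates used 9)
or selected by BIC: `ln det(Sigma_p) + p N^2 ln(n_eff)/n_eff` with
`n_eff` the total windowed sample count across trials; ties go to the
smaller order. On simulated order-2 ground truth BIC recovers the true
order in ~100% of runs at 40 trials x 300 samples.

PDC from channel j to i at frequency f is
`|Abar_ij(f)| / sqrt(sum_k |Abar_kj(f)|^2)` with
`Abar(f) = I - sum_r A_r exp(-i 2 pi f r / fs)`; each column's squared
entries sum to 1 (checked to 1e-10 as an invariant). Band matrices
average PDC over a 0.25 Hz grid spanning 4-7 Hz (13 points; halving the
step changes band means by <1e-3 on test models). The 380 ordered
off-diagonal entries are features.

Edge significance uses phase-randomized surrogates: per channel and
per trial, Fourier phases are replaced by independent uniform draws
(Hermitian symmetry preserved, amplitude spectra untouched), the model
is refitted and band PDC recomputed; the per-edge threshold is the
(1 - alpha) quantile of 5,000 surrogates at alpha 0.05 by default.
Randomizing per channel as well as per trial is required for a
causality null — phases must be scrambled *between* channels.
Thresholded matrices (sub-threshold edges zeroed) are the default
feature source; raw matrices are available via
`--no-surrogate-threshold`, since published analyses of this kind
rarely state which variant fed the classifier.

## Feature selection and classification

PLI and PDC features are fused into a 570-column table (at 20
channels). Features are ranked by the two-class Fisher score
`(mu1-mu2)^2 / (s1^2+s2^2)` with unbiased class variances; if both
variances vanish the score is 0 for equal means and a large cap
otherwise. Three strategies are searched: top-N PLI only, top-N PDC
only (N = 1..50), and a combined grid over totals L = 2..50 split into
top-n PLI + top-m PDC (n = 1..L-1). Each candidate is evaluated by
LOOCV with a linear SVM (libsvm via scikit-learn, C = 1, the LIBSVM
default; configurable); features are standardized by training-fold
mean/SD. Accuracy, specificity, sensitivity (patient group positive)
and AUC (pooled decision values, one per subject) are reported; the
best configuration maximizes accuracy with ties broken toward fewer
features, then higher AUC.

Two ranking modes exist. The default recomputes the Fisher ranking
inside every training fold, so the held-out subject never influences
selection. `--paper-faithful` ranks once on all subjects before LOOCV,
mirroring the common published practice; its accuracies are optimistic
and the mode exists for comparability only.

Classifier significance uses a modified permutation test: each
permutation shuffles every feature column independently (breaking
feature-label *and* feature-feature alignment), reruns the full LOOCV
and records the accuracy; `p = (1 + #{ACC_rand >= ACC}) / (1 + N)`
(add-one smoothing so p is never 0; the raw ratio is available).
Per-feature group differences use the two-sample rank-sum test — the
groups are independent, so a paired signed-rank test would be
inapplicable — with Benjamini-Hochberg FDR correction
across the selected set, reporting group means ± SEM and the direction
of the median difference.

## Synthetic ground truth

The generator produces two-group studies in which every downstream
claim has a recoverable truth. Each subject is a stationary MVAR trial
ensemble drawn from a base model — order-2 resonators at 6 Hz (pole
radius 0.65) with weak (0.01) nearest-neighbour coupling — perturbed
per subject by Gaussian coefficient noise (SD 0.005), with stationarity
enforced by bounded retries that halve the jitter. Directed truth is a
lag-1 coefficient delta on named edges, applied to one group only.
Undirected truth superposes a narrow-band oscillator pair whose phase
lag is consistent across trials (Gaussian jitter) in one group and
uniform in the other, with independent amplitude envelopes so only
phase carries the effect. Optional instantaneous mixing emulates
volume conduction. Trials discard a 100·p sample burn-in; everything
is bit-reproducible from the seed, and ground truth is stored in the
manifest, never passed to estimators.

Default geometry mirrors the emulated recordings: 48 trials, 768
samples at 256 Hz, onset mid-epoch, 20 channels. The end-to-end
strategy-ordering experiments use reduced conditions — 20+20 subjects,
10 channels, 24 trials, 384-sample epochs, fixed order 3, selection
grids to 10, surrogate thresholding off — sized so a full 25-study
replication completes in minutes on one CPU. Planted effect sizes
(directed delta 0.04, phase jitter 0.95 rad vs uniform) were chosen so
single-modality accuracies land in the 70-100% band reported for real
EEG connectivity classifiers rather than saturating at 100%, which
would make the strategy comparison vacuous.

What the generator does **not** emulate: ERP waveform morphology and
nonstationarity (the MVAR background is stationary within trials),
realistic head-model mixing (a single global matrix at most),
1/f broadband structure, artifacts, or behavioural-task effects.
Passing tests therefore demonstrate correctness of the estimators and
calibration of the statistics under the stated model, not clinical
performance on recorded EEG.

## Numerical choices and degenerate inputs

- Half-open windows everywhere; baseline must precede onset.
- Surrogate FFT keeps DC (and Nyquist for even lengths) real.
- Cluster connectivity is 4-neighbourhood; clusters must strictly
  exceed the null percentile.
- Cluster-test calibration uses smoothed noise maps (Gaussian sigma 2):
  wavelet power maps are smooth, and unsmoothed iid pixels leave the
  integer cluster-size null so heavily tied at 1-2 pixels that the test
  becomes far more conservative than its nominal level.
- `sgn(0) = 0` in the PLI with a relative 1e-9 zero tolerance.
- Fisher score of a constant feature is 0; zero-variance-but-separated
  features are capped, not infinite.
- Estimated models with companion spectral radius >= 1 warn rather than
  fail (finite-sample fits can be marginally unstable); ground-truth
  simulation refuses unstable models outright.
- All-identical feature values give p = 1 in the rank-sum comparison.

## Known limitations

- The surrogate threshold refits the full MVAR per surrogate; at the
  reference setting (5,000 surrogates, 20 channels, order 9) this is
  minutes per subject and is therefore disabled in the reduced
  synthetic experiments (both modes are unit-tested at small scale).
- LOOCV with within-fold ranking is O(subjects) SVM fits per candidate
  set; the combined grid at L = 50 over 75 subjects is the expensive
  corner of the original design and is exercised here at reduced grids.
- The pooled-variance t assumes equal group variances (the plain
  two-sample t is the reference choice here); Welch is not offered.
- AUC is computed from pooled LOOCV decision values, a common but not
  unique convention.
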