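# Methods

`nvfuse` implements a resting-state analysis of simultaneous EEG and fNIRS
recordings over the prefrontal cortex (PFC): an electrophysiological arm
built on the synchronization likelihood (SL), a hemodynamic arm built on
Pearson connectivity of oxygenated-hemoglobin (HbO) concentration changes,
permutation-based group inference with cluster correction, and a multimodal
source-power-comodulation (mSPoC) decomposition that couples EEG band power
to HbO dynamics. A synthetic-data generator plants every effect the pipeline
is meant to recover, so each stage can be verified without access to patient
recordings.

## EEG preprocessing

Raw EEG (64 scalp channels, native 2048 Hz, microvolts) is processed in a
fixed order: ocular correction, band filtering, decimation, epoching.

* **Ocular correction** is multichannel least-squares regression on the EOG
  channels: each scalp channel has its projection onto the (demeaned) EOG
  subspace subtracted, leaving residuals orthogonal to every EOG trace. A
  rank-deficient EOG set falls back to the pseudo-inverse. Regression is
  transparent and testable; ICA-style decompositions are out of scope.
* **Band filtering** uses zero-phase (forward–backward) 4th-order
  Butterworth band-passes over the canonical registry: delta 1.5–4 Hz,
  theta 4–8, lower alpha 8–10, upper alpha 10–13, beta 14–30, gamma
  30–50 Hz. Filtering precedes decimation so no aliasing enters the bands.
* **Decimation** (2048 → 256 Hz for analysis; 50 → 5 Hz for hemodynamic
  features) is anti-aliased integer decimation (`scipy.signal.decimate`,
  zero-phase), cascaded for large factors; a rational-resampling path exists
  but must be requested explicitly.
* **Epoching** drops the first 120 s (settling-in), cuts contiguous
  non-overlapping 2-s epochs (half-open sample windows, 0-based), rejects
  any epoch whose broadband absolute amplitude exceeds 150 µV on any
  channel, demeans each kept epoch per channel, and keeps the first 10
  survivors (5120 samples at 256 Hz). Rejection is evaluated once on the
  broadband signal so all bands share identical kept-epoch indices; this is
  required for cross-band comparability.

## Synchronization likelihood

SL is a nonparametric generalized-synchronization statistic. Signals are
delay-embedded (dimension m, lag tau); for each reference vector a critical
distance is set at the empirical p_ref-quantile (linear interpolation) of
the Euclidean distances to neighbours in the window w1 < |i−j| ≤ w2 (Theiler
window w1 excludes autocorrelated neighbours). The pairwise statistic counts
coincident recurrences normalized by p_ref · n_valid and averages over
reference times; it is exactly symmetric, affine-invariant per channel, and
calibrated: independent signals give ≈ p_ref, identical signals ≈ 1.

Embedding parameters derive per band from a frequency-adaptive rule:
tau = round(fs / (3·f_high)), m = round(3·f_high/f_low) + 1,
w1 = 2·tau·(m−1), w2 = w1 + round(n_rec / p_ref). For lower alpha at 256 Hz
with p_ref = 0.05 this yields (m, tau, w1, w2) = (5, 9, 72, 272). All five
parameters are overridable. With 2-s epochs the outer window exceeds the
per-epoch vector budget, so whole-head matrices are computed in
`concatenate` mode (epochs joined before embedding); `per_epoch_mean`
remains available for long epochs and raises a parameter error otherwise.
The implementation precomputes per-channel recurrence masks (vectorized,
blocked over reference times) and is verified to 1e-12 against a naive
O(M²) double-loop reference.

Quantile-grid note: the estimator's identical-signal ceiling is exactly 1
only when p_ref · n_valid falls on the empirical-quantile grid; off-grid
configurations carry a small positive bias of order 1/(p_ref·n_valid),
visible in the unit tests' window choices.

## fNIRS processing

Dual-wavelength (690/830 nm) optical density converts to concentration
changes via the modified Beer–Lambert law,
ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_Hb(λ)·ΔHb]·d·DPF(λ), solved as a 2×2 linear
system per channel and time point. Shipped extinction coefficients
(1/(µM·cm)): 690 nm — HbO 2.764e-4, Hb 2.052e-3; 830 nm — HbO 9.740e-4,
Hb 6.930e-4; source–detector distance 3 cm; DPF 6.0 at both wavelengths.
All are configurable; absolute micromolar scale is convention-dependent and
cancels in every correlation-based statistic downstream.

Cleaning: linear detrend, then zero-phase 3rd-order Butterworth band-pass
0.01–0.1 Hz (detrend first is numerically safer for the 0.01 Hz edge; a
strict band-pass-then-detrend order is available by flag). Records shorter
than three time-constants of the high-pass edge relax the edge with a
warning. Motion correction follows the moving-SD/spline paradigm: samples
whose 2-s moving SD exceeds 3× the quiet baseline (the lower quartile of
the moving SD — robust even when artifacts dominate the record) mark
artifact segments (gaps under 0.5 s merged); a smoothing spline (MATLAB-style
parameter 0.99, penalty (1−p)/p on the sample grid) is fitted per segment
and subtracted, and segments are re-levelled to their 1-s flanking means.
Channels with more than half their samples flagged are excluded rather than
corrected. Low-SNR screening flags a channel when its 1-s moving average
strays beyond 5 channel SDs from the channel mean for at least 1 s in either
chromophore; exclusions carry reason strings and are enforced downstream.

## Hemodynamic connectivity

Pearson correlation over HbO time courses of all retained channels gives a
symmetric matrix (14×14 at full montage). Fisher z = atanh(r) is applied
before any across-subject averaging or t-testing; displayed matrices remain
in r units (group means are back-transformed tanh of mean z). The network
graph keeps the foremost 5% of connections: the cut r_T is the k-th largest
off-diagonal of the *reference* matrix (the control-group mean, applied to
both groups), k = ceil(fraction·n(n−1)/2), ties at r_T all retained. Degree
strength σ_i is the mean of row i (diagonal excluded) of the full,
unthresholded matrix. Hb-based matrices are computed and written but do not
enter fusion.

## Group inference

All group tests are label permutations with the add-one estimator
p = (1 + #{null ≥ obs})/(1 + B), which cannot return zero; B defaults to
1000. The scalar test (e.g. per-band mean SL) uses the Welch t as its
statistic — chosen for the unequal group sizes (11 vs 8) this design
targets. Edgewise maps apply the Welch t per connection (on Fisher-z values
for correlations, raw for SL). Cluster correction: supra-threshold edges
(uncorrected p < 0.05) are grouped by the rule "edges are adjacent iff they
share an electrode endpoint" (connected components of the supra-threshold
edge set); cluster mass is Σ|t|; the null is the maximum cluster mass over
whole-subject label permutations. Covariates (age, gender, IQ) can be
residualized out of subject-level statistics before permutation
(Freedman–Lane-style). Demographic tables use two-sample t tests with
Bonferroni correction.

## mSPoC fusion

Features: per 2-s epoch, the channel covariance C_e of the band-filtered
EEG and the window mean of each fNIRS channel's ΔHbO after 5 Hz decimation,
with the fNIRS window shifted by `lag_epochs` epochs (the pipeline default
is 3 epochs = 6 s, the canonical HRF peak). The decomposition finds a filter
pair (w_eeg, w_fnirs) maximizing the correlation between the EEG power
series φ(e) = w_eegᵀC_e w_eeg and the projected hemodynamic series. The
alternating solver iterates three updates: z-scored φ; ridge-regularized
regression for w_fnirs with λ = 0.1·(trace/F) — substantially stronger than
a nominal jitter because the regression otherwise overfits a 14-channel
feature set at any realistic epoch count; and a spatial-filter step that
solves the generalized eigenproblem of (Σ_e t(e)C_e, mean C), scores every
eigenvector by the correlation it actually achieves (the top eigenvector
maximizes covariance, which is not the objective), and refines within the
2-D span of the two best candidates over an angle grid (eigenvectors are
orthonormal in the mean-covariance metric, so any combination keeps
w_eegᵀ·meanC·w_eeg = 1). Initialization: deterministic seeds from the
leading principal components of the fNIRS features first, then random
restarts; the best converged solution wins. On a 2-channel × 2-channel toy
problem the solver matches an exhaustive 0.5°-grid filter search to ~1e-6
in r.

Significance is assessed by refitting under circular shifts of the epoch
pairing. Shifts preserve the autocorrelation both feature streams share — a
full shuffle destroys it and overstates significance severely (34% false
positives at α = 0.05 in our null calibration, versus 3–7% for shifts).
Shifts shorter than min(n/4, 5) epochs are excluded from the null because
they do not break a genuine coupling whose envelope correlation time is a
few seconds. Consequence: the subject-level p-value has a floor of roughly
1/n_epochs, so 10-epoch fits report coarse p-values; significance claims
belong to longer records or to the group level. Activation patterns are
a = C w at unit source power (w scaled so wᵀCw = 1), sign-fixed so the
largest-magnitude EEG entry is positive; patterns, not filters, are the
physiologically interpretable output. One component is extracted by
default; further components deflate the pattern directions from both
modalities. ROI-wise fusion selects electrodes/channels per montage ROI
tag (left/right dlPFC and frontopolar sets, plus the whole-PFC pool) and
reports per-group mean r with s.e.m. over subjects and sign-aligned average
patterns.

## Synthetic data

The generator emulates 11-minute eyes-closed bimodal records.

* **EEG sources**: per-electrode band-limited Gaussian noise (4th-order
  Butterworth in the configured band) modulated by smoothed positive
  random-walk envelopes. Envelope time constant 6 s and modulation depth
  0.6 — slow enough for the HRF to track, fast enough that an 11-minute
  record holds ~90 independent power fluctuations. Electrodes joined by
  synchrony pairs form connected components sharing one common source with
  weight κ against (1−κ) private signal, so stars and chains synchronize
  transitively (as generalized synchrony does in practice). A designated
  "neurovascular" source enters the EEG with a smooth spatial profile.
  Background: 1/f noise (slope −1) plus white sensor noise, mixed by
  `noise_mix`; channels scale to 20 µV RMS. Optional 300-ms biphasic blink
  transients load frontal rows and the EOG channels.
* **Hemodynamics**: ΔHbO follows the HRF-convolved *power* envelope of the
  designated source — band power is the quantity the EEG arm measures, and
  power comodulation is exactly the model-class assumption — scaled by a
  signed coupling gain β across a smooth 14-channel spatial pattern, mixed
  with per-channel 1/f noise; ΔHb = −0.3·ΔHbO plus noise. The HRF is a
  double-gamma kernel (unit peak at 6 s, undershoot near 16 s, ratio 1/6,
  32 s support). Optical density is emitted through the same forward
  Beer–Lambert operator the pipeline inverts; optional motion spikes load
  the OD rows.
* **Cohorts**: group A at nominal parameters, group B "patient-like" with
  κ scaled by 0.6 and β by 0.5 (both configurable); group sizes default to
  11 vs 8; per-subject seeds spawn deterministically from the cohort seed.

What the generator does **not** emulate: volume conduction and realistic
leadfields, pulse/respiration/Mayer waves, heteroscedastic electrode noise,
scalp-coupling failures, or any nonstationarity beyond the planted
envelopes. Passing recovery tests therefore demonstrates algorithmic
correctness and calibration on in-model data, not field performance on
clinical recordings.

## Verification scales and numerical choices

Monte-Carlo suites run at reduced scales chosen to keep the whole test run
on one CPU within minutes: SL calibration uses the full 5120-sample
(10-epoch) windows at p_ref = 0.05; cohort-level suites (type-I error,
family-wise cluster control, planted-star recovery, group-direction
detection) use 5–9-channel montages, 150-s records, and fast SL windows
(p_ref = 0.1, n_rec = 5); mSPoC recovery uses 8 EEG × 14 fNIRS channels at
full 11-minute length with 250 epochs and lag 3. The family-wise false
positive assertion allows the two-sigma binomial envelope around the 5%
rate over 100 cohorts. Degenerate inputs raise typed errors (constant
series in SL, zero pooled variance in permutation tests, singular extinction
matrices); ties in the threshold rule are kept; quantiles interpolate
linearly; all randomness flows through explicit integer seeds and
`numpy.random.SeedSequence` spawning.

## Known limitations

* SL absolute values depend on the embedding configuration; between-group
  contrasts are meaningful, absolute levels are not comparable across
  parameter choices.
* The 16-bit EDF container quantizes amplitudes to the channel span over
  2^16; round trips are exact only to that resolution.
* Subject-level mSPoC p-values are grid-limited by the circular-shift count
  (~1/n_epochs).
* The 1/f hemodynamic noise leaves few effective degrees of freedom in the
  0.01–0.1 Hz band, so chance correlations up to ~0.3 with any slow
  reference are normal at these record lengths; inference must rely on the
  permutation machinery, not raw correlation magnitudes.
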