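# Methods

This note documents the models behind `nirsac`, the rationale for the fixed
parameters, and known limitations.

## Probe model

The probe is a spherical-head layout (radius 87.5 mm) with 16 regular channels
(30 mm source–detector separation) partitioned into three regions of
interest — SMA (channels 1–4), left M1 (5–10), right M1 (11–16) — and 8
short-distance channels (SDCs, 8 mm separation) interleaved across the
array. Channel positions live on the scalp sphere; inter-channel distances
are great-circle angles used by the GCR smoothing kernel, and the
Euclidean-nearest SDC defines the SSR regressor. Each task condition has an
a-priori ROI: semisimulation (SIM) and right-hand execution map to left M1,
left-hand execution to right M1, motor imagery to SMA.

## Synthetic generator

Two-wavelength (760/850 nm) intensities are sampled at 7.8125 Hz. Systemic
activity (SA) is built per hemoglobin species as a sum of four narrowband
components:

| Component | Center (Hz) | Amplitude (µM HbO) | Bandwidth (Hz) |
|-----------|-------------|--------------------|----------------|
| slow vasomotion | 0.04 | 4.0 | 0.02 |
| Mayer waves | 0.10 | 3.0 | 0.03 |
| respiration | 0.25 | 1.5 | 0.06 |
| cardiac | 1.10 | 1.0 | 0.15 |

Each band mixes a global trace (share 0.5) with channel-local traces
correlated over a 25 mm spatial scale, and each channel gets a per-band
gain drawn from U[0.5, 1.5]. HbR systemic activity is 0.3× the HbO
amplitude and correlated 0.7 with the HbO field rather than being a scalar
copy. These values were fixed from the qualitative requirements the
comparison presumes — substantial SA power inside the 0.01–0.09 Hz analysis
band, and SA that is heterogeneous across channels, SDCs and species (so
that the nearest SDC is informative but not a duplicate of any regular
channel) — before any method ranking was evaluated, and were then frozen.
White measurement noise (sd 1.0 µM-equivalent) is added, and the µM signals
are mapped to intensities by inverting the modified Beer–Lambert law with
age-dependent differential pathlength factors.

For the real-task recordings, an additional task-evoked SA component (1.5 µM
peak) is shared by regular channels *and* SDCs, which is what gives
SDC-based corrections their advantage and CAR/GCR their overcorrection
risk. The semisimulation recording deliberately has no task-evoked SA.

## Preprocessing

1. **Channel quality**: scalp coupling index (SCI, cardiac-band correlation
   of the two wavelengths), peak spectral power (PSP) and the fraction of
   good 5 s windows (Q); thresholds 0.6 / 0.1 / 0.65. Failing channels are
   pruned (set to NaN) and propagate as NaN through every later stage.
2. **Optical density**: −ln(I / mean(I)) per channel and wavelength.
3. **TDDR motion repair**: robust Tukey-bisquare reweighting of the ≤0.5 Hz
   band of the temporal derivative, re-integrated, with the >0.5 Hz residual
   added back.
4. **Modified Beer–Lambert law**: 2×2 extinction solve per sample with
   age-dependent DPF and a partial-volume scaling of 1/60.
5. **Semisimulation injection**: canonical HRFs (difference of gammas, unit
   peak at 6 s) scaled to 10/5 µM HbO (−1/3 for HbR) are added at trial
   onsets of the schedule.
6. **Band-pass**: zero-phase 2nd-order Butterworth, 0.09 Hz low-pass then
   0.01 Hz high-pass.

### TDDR distortion bound

The published TDDR algorithm cannot pass a pure low-frequency sinusoid
through unchanged: the sinusoid's derivative is itself sinusoidal, so its
peaks carry the largest normalized residuals and are shrunk hardest by the
bisquare weights. The distortion is scale-invariant and measures ~8% of
amplitude at 0.05 Hz; the test suite bounds it at 10% and separately checks
<1% passthrough for >0.5 Hz content (which bypasses the repair) and >90%
suppression of large slow motion artifacts.

## Corrections

All corrections act per species on the 16 regular channels; SDC rows pass
through untouched.

- **CAR** subtracts the per-sample mean over non-pruned regular channels.
  Algebraic consequence: injected responses leak into every channel — with
  10 + 5 µM injected into 2 of 16 channels, every channel loses 15/16 µM of
  the HRF shape, so CAR can never satisfy a "<2% peak error" recovery
  property. The tests check CAR against this exact prediction.
- **GCR** SVD-decomposes the channels × time matrix, smooths each spatial
  singular vector with a row-normalized Gaussian kernel over great-circle
  distances (σ = 46°), reconstructs the smoothed ("global") part and
  subtracts it. With an identity kernel the method removes everything — an
  algebraic identity used as a test.
- **SSR** removes α·SDC from each channel with the least-squares scalar α
  against the Euclidean-nearest non-pruned SDC; the residual is orthogonal
  to the regressor by construction.
- **GLM_ALL / GLM_BH** regress each channel on an intercept plus the
  mean-centered time courses of all 8 (or 2, one per hemisphere) SDCs of
  *both* species — 16 or 4 SA regressors — using AR-IRLS, and keep
  `Y − X_SDC·β_SDC`. Only the SDC contribution is subtracted; the fitted
  intercept (channel offset) is retained.

## AR-IRLS

Task GLMs and the GLM corrections use a robust prewhitened solver: the AR
order of each channel's residual is chosen by BIC via Levinson–Durbin
recursion (up to order 32), data and design are filtered by the AR
polynomial, and Tukey-bisquare IRLS (c = 4.685) with sandwich standard
errors is iterated to convergence. Calibration under AR(1) noise (φ = 0.6,
n = 2000, 200 replicates): empirical 95% CI coverage 0.96, versus 0.72 for
naive OLS.

## Evaluation

Trials are epoched [−5, 25) s and baseline-corrected with the pre-onset
mean. Per selected channel (strongest ROI activation in the GLM_ALL task
GLM; highest beta for HbO, lowest for HbR):

- **sRMSE**: min-max scale epoch and canonical-HRF template to [0, 1],
  regress epoch on template with intercept, report the RMS residual (lower
  is better).
- **COR**: Fisher-z-transformed Spearman correlation with the template
  (clamped at |ρ| = 1 − 10⁻⁷ before atanh).
- **CNR**: (mean of the ±2 s window around the post-onset peak − baseline
  mean) / √(var_task + var_base).

For HbR the template is sign-flipped and CNR negated so larger is always
better. Spatial specificity: trial-averaged 24×24 Spearman matrices whose
SDC rows always come from the *uncorrected* epochs, compared between
methods by paired JZS Bayes-factor t-tests over the 276 lower-triangular
entries (120 tests: 15 method pairs × 4 tasks × 2 species), and group beta
maps with one-sample Bayes factors per channel.

## Scale of the shipped comparison

The default cohort is deliberately desk-sized: 6 subjects, 5 semisimulation
trials, 4 trials per real-task condition (~150 s total runtime). Metrics
are therefore noisier than a full-size study; the qualitative group-level
contrasts (SDC methods best, CAR/GCR overcorrection) are stable across
seeds, individual metric values are not.

## Known limitation: GLM_ALL does not rank first on SIM

Under strong shared SA one would expect the 16-regressor GLM correction to
rank first on the semisimulation metrics; here SSR does (group-mean sRMSE
0.104 vs 0.136). The cause is record length, not the solver: a ~200 s
recording band-passed to 0.01–0.09 Hz retains only ~30 effective temporal
degrees of freedom, and 16 SA regressors absorb a measurable share of the
injected response itself (HRF retention ~0.90 with AR prewhitening, lower
with OLS), while SSR spends a single degree of freedom. With longer
recordings the trade-off reverses. The acceptance test encoding the
expected ranking (`test_criterion_5c_glm_all_first_on_sim`) is left failing
rather than weakened; all oracle and algebraic-identity tests for the GLM
machinery pass.
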