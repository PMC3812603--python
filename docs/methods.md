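# Methods

## Problem and signal model

The package classifies one-second stretches of single-channel prefrontal
(Fp1) EEG as *attentive* or *inattentive*. The working assumption, standard
in attention neurophysiology, is that the state is visible in the relative
power of the conventional wavebands: frontal β (14–30 Hz) rises with alert,
engaged cognition, while θ (4–7 Hz) and α (8–13 Hz) rise with relaxation and
disengagement. The classifier therefore sees only band powers, never the raw
waveform.

The acquisition model is a consumer dry-electrode headset: one channel,
512 Hz sampling, 16-bit quantization, with the per-second attention labels
supplied externally (in the intended application, by human curation of the
recording session; labels may also be `discard` for ambiguous seconds).

## Processing chain

1. **Low-pass filter, 50 Hz.** Order-4 Butterworth applied forward and
   backward (`scipy.signal.sosfiltfilt`), giving zero net phase shift and a
   maximally flat passband. All featurized bands lie at or below 30 Hz,
   where the double-pass response is within 0.2 % of unity; the gentle
   roll-off between 40 Hz and Nyquist is irrelevant to the features. The
   family and order are configurable (`filter.family`, `filter.order`);
   order 4 is the default because higher orders buy nothing below 30 Hz and
   are numerically touchier. No mains notch is applied — the 50 Hz low-pass
   already sits on the European mains frequency.
2. **Windowing.** 512-sample windows, 256-sample hop (1 s windows, 0.5 s
   overlap at 512 Hz). No padding: trailing samples that cannot fill a
   window are dropped, so every window feeds the FFT exactly 512 points.
3. **Labeling.** A window inherits the common label of every second it
   touches; any disagreement, or contact with a `discard` second, discards
   the window (unanimity rule). This mirrors curation practice — ambiguous
   epochs are excluded rather than guessed — and resolves the question of
   how half-overlapping windows straddling a state change should be labeled.
4. **Spectrum.** The periodogram of the unwindowed FFT, `P(n) = |F(n)|²/N`
   with `N = 512`. No taper is the default (a Hann taper is available as
   `psd.taper: hann` for leakage-sensitive uses). With this normalisation
   `Σ P(n) = Σ x(t)²` exactly (Parseval), which the tests assert to 1e-9.
5. **Features.** One-sided band energies over bins whose center frequency
   (bin n = n Hz here) falls in α [8,13], β [14,30], θ [4,7], δ [1,3] Hz,
   plus the ratio `R = E_α/E_β`. Conventions worth noting:
   - δ nominally starts at 0.5 Hz, but 1-Hz bins have no 0.5 Hz bin; δ sums
     bins 1–3. DC is excluded — it carries electrode offset, not rhythm.
   - Sums are one-sided without the conventional factor 2; the features are
     used comparatively and in a ratio, so a global constant cancels.
   - γ (31–50 Hz) exists in the signal model but is never featurized; the
     classifier uses exactly five features.
   - A window with vanishing E_β (exactly zero, or ≤ 1e-9·E_α — FFT
     round-off territory) has no defined R and is excluded, with a count
     logged.

## Classifier

`AttentionSVC` is a soft-margin SVM with one of two polynomial kernels,

    polykernel             K(x,y) = (x·y + 1)^d
    normalized polykernel  K(x,y) / sqrt(K(x,x) K(y,y))

implemented in `eegattn.kernels` and injected into libsvm's SMO solver
(scikit-learn `SVC`) as a Gram-matrix callable, so the kernel arithmetic
exercised in production is the package's own. Defaults: degree `d = 2`
(degree is rarely reported for this task; 2 is the smallest degree that
yields a non-linear boundary, and the ablation harness can sweep it), cost
`C = 1`, SMO tolerance 1e-3, iteration cap 1e6 so a non-converging
configuration raises a warning and stops rather than spinning.

**Standardization is on by default.** Raw band energies span orders of
magnitude (δ near 10⁴ μV², β near 10²), so un-scaled polynomial kernel
values reach ~10¹⁶ and the dual solver effectively sees only the δ axis and
fails to converge in any useful time. Features are z-scored with
training-set statistics (stored on the model, applied at prediction);
`standardize=False` exposes the raw-kernel behaviour for anyone who wants
the literal un-scaled reading.

Class mapping is attentive → +1, inattentive → −1. A decision value within
1e-6 of zero (below SMO resolution) is treated as a tie and resolved to
*attentive*: in the classroom application a false "inattentive" alarm is
the costlier error.

Models serialize to a version-tagged JSON archive (kernel spec, C, scaling
statistics, support vectors, dual coefficients, bias) and round-trip to
identical predictions.

## Evaluation protocol

Stratified 5-fold cross-validation (class-balanced folds; with 2,400 rows
per class each fold tests 480 rows, 240 per class). Reported per
configuration:

- per-fold test accuracy, its mean and maximum ("highest accuracy");
- per-fold training (resubstitution-on-training-folds) accuracy, mean and
  maximum;
- attention rate `AR = CA/TA·100` and inattention rate `IR = CI/TI·100`
  pooled over the k test folds, plus full-data resubstitution counts;
- a normal-approximation 95 % binomial CI on the pooled accuracy (no
  multiple-testing correction is applied across ablation cells; the CI is
  the honesty device);
- prevalence-weighted overall accuracy `AR·(1−p) + IR·p` for an assumed
  inattentive time fraction p (default 0.1).

With balanced folds, pooled accuracy equals (AR+IR)/2 exactly; the tests
assert the identity. The ablation grid evaluates the full five-feature set
and each leave-one-feature-out subset, for both kernels — 6 subsets × 2
kernels × 4 accuracy rows. Grouped evaluation trains fully independent
classifiers per metadata group (the intended use: one per gender), with no
information crossing groups; a group lacking both classes is skipped with a
warning.

## Synthetic data

No public attentive/inattentive EEG corpus exists for this recording setup,
so the generator simulates the study conditions. Per second, each of the
five bands contributes a band-limited random-phase component (white noise,
order-4 Butterworth band-pass, forward-backward) whose sinusoid-equivalent
amplitude (RMS·√2) is drawn uniformly from the conventional resting ranges —
δ 100–200, θ 10–30, α 30–50, β 5–20, γ 5–10 μV — times a per-state gain:
attentive β ×1.5, α ×0.8, θ ×0.7, others ×1.0; inattentive all ×1.0.
Broadband Gaussian noise (default σ = 5 μV, a plausible dry-sensor floor,
small against every band) is added, and Poisson-timed exponential bursts
(~100 ms, default off) emulate dry-electrode motion artifacts. Components
are phase-continuous within a state block; per-subject streams are seeded
counter-style from (seed, subject index) so cohorts grow without
reshuffling. Filtered noise, not pure tones, is deliberate — it exercises
spectral leakage and window effects; a pure-tone path exists only in tests,
where exact-bin sinusoids provide closed-form expected values.

The standard cohort used by the acceptance script is 24 subjects (12 M /
12 F), 42 s per state each — ≈ 83 windows per state per subject, ≈ 2,000
windows per class after labeling — sized so the full protocol runs in
seconds while keeping binomial noise on accuracies below half a percent.

**What the generator does and does not establish.** Passing the end-to-end
tests shows the pipeline recovers a band-power state difference of the
configured size from realistically noisy spectra, and reports chance when
no difference exists (equal gains). It does not establish performance on
real EEG: the generator has no 1/f background, no eye-blink or EMG
waveforms, no inter-subject spectral idiosyncrasy, and its labels are
noiseless. One property deserves emphasis: because per-second band
amplitudes are drawn uniformly from the full resting ranges, the two
classes' amplitude distributions overlap substantially, and the overlap —
not the pipeline — bounds achievable accuracy. Working through the three
informative bands' uniform densities gives a Bayes-optimal balanced
accuracy of ≈ 88.6 % even with error-free amplitude recovery; finite-window
periodogram noise (χ² with ~12–34 degrees of freedom per band energy) costs
roughly another ten points. The observed mean 5-fold accuracy near 77 % is
therefore a property of the simulated task's difficulty, not a ceiling of
the method — and it lands in the same range typically reported for
single-channel frontal-EEG attention classification on real data.

## Numerical choices, degenerate inputs

- FFT: `numpy.fft` double precision; agreement with an independent O(N²)
  DFT-matrix oracle is asserted to < 1e-9 relative.
- Recordings shorter than one window yield zero segments with a warning,
  not an error; an empty label track is valid until validated against a
  recording.
- Recordings at fs ≠ 512 are readable, but the pipeline default is
  `strict_fs: true` (refuse); polyphase resampling to 512 Hz is opt-in,
  because every downstream constant (1 Hz bins, 512-point windows) assumes
  the native rate.
- EDF output quantizes to 16 bits over the recording's own physical range;
  round-trip error is bounded by one quantization step. EDF pads the last
  partial 1-s record with zeros.
- Determinism: every stochastic step (generator, fold shuffling) takes an
  explicit seed; rerunning a config byte-identically reproduces the report.

## Known limitations

- Single channel, fixed 512/256 window schedule; no multitaper or Welch
  averaging (deliberately, to keep the feature definition exact).
- The normalized-kernel form is the standard self-normalized polynomial
  kernel; other normalizations exist in the literature.
- A temporal smoother (majority vote over consecutive windows) is a known
  accuracy lever but is intentionally outside the replicated protocol.
- The per-second amplitude redraws make seconds exchangeable within a
  state; real band power drifts with slower autocorrelation.
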