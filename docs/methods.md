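# Methods

This note documents the processing model, its tunable parameters, the
numerical choices made where the definition left room, what the synthetic
generator does and does not emulate, and the known limitations.

## Signal model and assumptions

Arm swing is modeled as a rotation of the forearm about a single transverse
axis with a periodicity of 0.3–3 Hz. The wrist sensor reports angular
velocity in its own right-handed frame with z along the forearm; the swing
plane's orientation within the transverse (x, y) plane is unknown and may
vary between wearings, which is why the swing-direction velocity is
extracted by principal component analysis of (x, y) rather than by assuming
an anatomical axis. Longitudinal rotations (turns, pronation/supination)
are excluded by construction. The pipeline assumes a uniformly sampled
recording (tolerance 1e-6 relative on the sample spacing) of at least 3 s
at ≥ 20 Hz; all reference behavior is established at 200 Hz.

## Parameters

All defaults live in `AnalysisConfig` and are overridable per run:

| parameter | default | unit | role |
|---|---|---|---|
| `cutoff` | 3 | Hz | zero-phase 2nd-order Butterworth low-pass |
| `band_low`, `band_high` | 0.3, 3 | Hz | admissible swing band |
| `power_gate` | 0.90 | — | min in-band share of non-DC window power |
| `fft_window_s` | 3 | s | spectral / peak-detection window length |
| `fft_overlap_freq` / `fft_overlap_peaks` | 0.75 / 0.5 | — | window overlaps |
| `prominence` | 2 | deg | min extremum prominence |
| `min_distance_frac` | 0.6 | — | min same-kind extremum separation, × per-window cycle time |
| `long_swing_factor` | 2 | — | max swing duration, × average cycle time |
| `outlier_factor`, `outlier_percentile` | 3, 80 | — | extremum outlier rule |
| `amp_threshold` | 5 | deg | min swing amplitude |
| `vel_threshold` | 10 | deg/s | min peak angular velocity |
| `regularity_window_s`, `regularity_cosine_fraction`, `regularity_overlap` | 4.5, 0.3, 0.99 | — | autocorrelation windows |
| `simultaneity_tol_s` | 0.5 | s | direction-change pairing tolerance |
| `eligibility` | 0.60 | — | min simultaneous share for bilateral indices |
| `max_gap_s` | 0.25 | s | longest NaN run the reader repairs |

## Numerical and interpretation choices

- **Zero-phase filtering.** "Zero-phase 2nd-order Butterworth" is realized
  as a 2nd-order design applied forward and backward (`filtfilt`), i.e. the
  squared single-pass magnitude. Passband consequence: a 1 Hz component is
  attenuated by ~1.2%, so measured amplitudes sit systematically ~1%
  below the generated ones; all recovery tolerances account for this.
- **PCA.** The principal direction is estimated from the mean-centered
  covariance; the raw channels are projected, so a rate bias survives until
  the detrend stage. The component sign is fixed by making the
  larger-magnitude loading positive (tie: x positive). Forward/backward
  labels are therefore reproducible conventions, not anatomical guarantees.
  The projection is computed once per bout, not per window.
- **Detrend.** The moving-average half-window is q = round(fs/2) samples
  (1.005 s window at 200 Hz). Edges are padded by replicating the first and
  last angle values so all series keep full length; the exact weighted
  average holds on the interior q < n < N − q, which is what the tests
  assert. Note the detrender is effectively a high-pass with substantial
  attenuation below ~1 Hz (gain 1 − H_MA: 0.36 at 0.5 Hz, 0.89 at 0.9 Hz,
  1.00 at 1.0 Hz at 200 Hz). This is inherent to drift removal with a ~1 s
  window and means slow swings are reported with reduced amplitude — by
  both this implementation and any reference following the same definition.
- **Spectral gate.** DC is excluded from both numerator and denominator of
  the band-power fraction (the gate measures periodicity, and the detrended
  angle is near zero-mean anyway); band edges are inclusive; the dominant
  frequency is searched over all non-DC bins up to Nyquist, and a dominant
  bin outside the band invalidates the window through the validity rule.
  Trailing partial windows are dropped. With 3 s windows the frequency
  resolution is 1/3 Hz, so e.g. a 0.9 Hz swing reports 1.0 Hz.
- **Extrema.** Maxima and minima are detected separately per window so the
  minimum-distance rule applies within each kind. Cross-window duplicates
  are identified by sample index; two same-kind detections closer than the
  minimum distance are treated as one physical peak and the larger
  magnitude is kept. Samples not covered by any valid spectral window are
  unanalyzable and their extrema are dropped. Alternation is enforced by
  discarding the smaller of two adjacent same-kind extrema (tie: the later
  one).
- **Peak velocity search** uses the closed swing interval; on
  equal-magnitude ties the earliest sample wins.
- **Retention order** is long-swing → outlier → amplitude → velocity, and
  only the first tripped rule is recorded. The outlier percentile is taken
  over all detected extremum magnitudes (pre-filter, post-alternation) with
  linear interpolation.
- **Regularity.** The autocorrelation is normalized by the tapered
  window's lag-0 energy (biased estimator), which keeps the ≤ 1 bound
  exact. The maximum is searched over lags 0.33 s (period of the fastest
  admissible swing) to half the window; without this exclusion the lag-0
  peak's shoulder would return ~1 for any signal. Because the biased
  estimator decays roughly like (1 − lag/window), a perfectly periodic
  1 Hz signal scores ~0.77, not 1; regularity is meaningful as a relative
  measure (periodic ≈ 0.7–0.8, noise < 0.1).
- **Coordination.** The symmetric lag range 0 ± 0.5 s is implemented by
  shifting either signal and normalizing by the energies of the overlapping
  segments, per simultaneous swing on its interval extended by 0.5 s on
  each side; every simultaneous swing of either arm contributes one score.
  Two caveats are inherent to the definition: for swing frequencies ≥ 1 Hz
  the lag range spans ≥ half a period, so in-phase and anti-phase arms both
  score near 1; and the finite correlation segments leave a small bias, so
  in-phase slow arms score ~0.2 rather than the idealized 0.
- **Asymmetry.** Means enter the ASI only from simultaneous-phase swings;
  the signed convention is left minus right over the larger of the two.
- **Agreement statistics.** The random error is the Bland–Altman limits-of-
  agreement half-width, 1.96 × sample SD (n−1) of the differences, with the
  sign convention test (wearable) minus reference.
- **Degenerate inputs** are signalled, not zero-filled: a motionless arm
  ("no swing axis"), a bout with no valid spectral window ("no periodic
  movement"), and an arm without retained swings all yield explicit status
  or `None` fields.

## Synthetic generator

The generator emulates the definition the pipeline targets: a sinusoidal
swing angle per arm with per-half-cycle lognormal amplitude jitter (so the
per-swing truth stays exact), an arbitrary constant phase offset between
arms (π = normal anti-phase gait), an arbitrary mounting rotation about the
forearm axis, constant rate bias, white sensor noise, a tremor sinusoid
(default 5 Hz, above the low-pass cutoff), and an optional longitudinal
turning profile. Presets encode three study conditions at 0.9 Hz: slow
healthy gait (~16° swings), brisk healthy gait (~36°), and a parkinsonian
pattern (~17° with ~36% amplitude asymmetry, higher jitter, tremor).

It does **not** emulate: pendulum biomechanics (amplitude–frequency
coupling, damped transients), within-bout frequency drift or 2:1
arm–leg-ratio transitions, non-sinusoidal swing waveforms, accelerometer
channels, or clock desynchronization between arms. Passing tests therefore
demonstrate correctness of the algorithmic chain on signals that satisfy
the arm-swing definition plus the modeled confounds — not robustness to
every artifact of free-living recordings.

## Problem sizes

Test and acceptance runs use 200 Hz bouts of 10–60 s: long enough for
≥ 50 swings, dozens of spectral windows, and >1000 regularity windows,
which the package processes in well under a second per bout. The retention
boundary sweeps run the full pipeline 37 times (amplitude, 0.25° steps)
and ~100 times (frequency, 0.005 Hz steps).

## Known limitations

- Walking itself is not detected; the pipeline quantifies any periodic
  0.3–3 Hz wrist rotation, so a gait detector should gate its input in
  free-living use.
- Sub-hertz swings are attenuated by the ~1 s detrend window (see above);
  with a 6° swing nothing below ~0.86 Hz survives the 5° amplitude gate.
  Consequently the 10 °/s velocity threshold is never the binding retention
  constraint for sinusoidal swings — any sinusoid passing the amplitude
  gate already exceeds it.
- Bilateral metrics require externally synchronized clocks; nothing is
  resampled or aligned.
- The frequency parameter inherits the 1/3 Hz bin resolution of the 3 s
  windows.
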