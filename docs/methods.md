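# Methods

## Processing model

A trial is one participant × session × activity recording set: per device
(test, criterion) and body location (sacrum, thigh, shank) a 60 Hz stream
of orientation quaternions (w, x, y, z) and free accelerations stored in
(z, x, y) axis order — the order every downstream table reports.

1. **Euler conversion.** Quaternions are decomposed with the intrinsic
   z–x–y sequence (scipy `Rotation`, `'ZXY'`), reported in degrees. The
   middle (x) angle is confined to (−90°, 90°) by construction; the outer
   angles are unwrapped (period 360°) so filtering never sees a wrap
   discontinuity. Gimbal proximity (|x| within 1e−6 of 90°) raises a
   warning but still returns values.
2. **Filtering.** 6 Hz low-pass second-order Butterworth, applied
   forward–backward (`filtfilt`). Zero phase is the default because phase
   lag would shift the test waveform against the criterion waveform and
   bias every agreement statistic; the single-pass variant and the
   filter-before-conversion ordering are config options
   (`RunConfig.zero_phase`, `RunConfig.filter_before_euler`), since
   either ordering is defensible. The effective dual-pass amplitude
   response is the *square* of the single-pass magnitude; note that for a
   digital (bilinear-transform) design this deviates strongly from the
   analog prototype formula 1/(1+(f/f_c)⁴) near Nyquist — at 25 Hz of a
   60 Hz stream the digital response is ~5.7e−5 against the analog
   3.3e−3 — so the package's filter oracle is the squared magnitude of
   the designed digital filter evaluated via `freqz`.
3. **Direction inversion.** For walking trials, the x and y acceleration
   axes are multiplied samplewise by +1/−1 direction flags so return-path
   strides contribute with consistent sign. Flags come from the trial
   manifest (annotation spans) or the recording's `direction` column;
   automatic turn detection is out of scope.
4. **Cycle detection.** On each device's *own* filtered
   thigh-orientation-x stream, dominant troughs are local minima with
   prominence ≥ 25 % of the stream's peak-to-peak range and separation
   ≥ 0.5 s (both configurable). A bare extremum rule is ill-posed on
   noisy signals; prominence + minimum-period is the standard
   peak-picking regularization. Cycle start/end are the nearest local
   maxima flanking each trough; edge-truncated cycles are dropped, then
   the first and last complete cycles are discarded.
5. **Time normalization.** Each segment (both endpoints included) is
   linearly interpolated onto 101 points (0–100 %); cubic-spline
   interpolation is available via config. The per-cycle outcome is the
   range (max − min), averaged over a participant's retained cycles;
   cohort summaries average participant means with equal weight, never
   pooling cycles.
6. **Pairing.** Test and criterion cycles are paired by cycle index
   (lists truncated to the shorter). No cross-device clock
   synchronization is assumed; time normalization makes index pairing
   meaningful.

## Statistics

* **LFM** (`LinearFit`): OLS of test on criterion
  (`scipy.stats.linregress`); α₁ slope, α₀ intercept, r² squared Pearson
  correlation. Fitted per participant on concatenated retained cycles by
  default (`mean_cycle` mode available), then summarized mean ± SD across
  participants; the case class comes from the mean r². Bands:
  r² ≥ 0.75 excellent, [0.40, 0.75) fair-to-good, [0, 0.40) poor — the
  printed bands leave 0.39 < r² < 0.40 undefined, so the implementation
  uses half-open intervals that make classification total.
* **Bland–Altman** (`BlandAltman`): differences are **criterion − test**;
  mean, SD (ddof = 1), limits of agreement mean ± 1.96·SD, t-based 95 %
  CI of the mean difference, pairwise means as plot abscissa. Both the
  CI and the LoA are emitted side by side in reports.
* **ICC** (`IntraclassCorrelation`): two-way random effects, consistency,
  single measures — ICC(C,1) — from the two-way ANOVA mean squares, with
  the standard F-based CI (df n−1 and (n−1)(k−1)). ICC(C,k) is available
  via `form="average"`. The estimate is clipped at 1 only against
  floating-point excess; negative estimates are reported as computed and
  classified poor. Cross-checked in the test suite against
  `pingouin.intraclass_corr` (estimate and CI agree to reporting
  precision).
* **SEM** = SD·√(1 − ICC), with SD taken across participants of each
  participant's mean of the two compared measurements (a literal reading
  of "SD of the mean values"; taking instead the SD of session 1 values
  is a one-line change on `sd_used`). On simulated cohorts SEM
  approximates the within-subject SD √σ_w² (checked within 10 % at
  n = 200).
* **Classification summaries**: counts and percentages per class over the
  case grid (3 locations × 3 axes × 5 activities = 45 cases per
  quantity), rounded half-up to one decimal (so 1/45 → 2.2 %,
  7/45 → 15.6 %).
* **Sample size** (`reliability_sample_size`): Walter–Eliasziw–Donner.
  The `approx` variant uses
  n = 1 + 2k(z_α+z_β)²/((k−1)(ln C₀)²) with
  C₀ = (1+kρ₀/(1−ρ₀))/(1+kρ₁/(1−ρ₁)); the `exact` variant searches the
  smallest n whose one-way F test of H₀: ρ = ρ₀ reaches power 1−β at
  ρ = ρ₁. For (α = 0.05 one-sided, β = 0.2, k = 3, ρ₀ = 0.4, ρ₁ = 0.7)
  these give n = 21 and n = 20; two-sided α gives 26/25. The exact
  variant's power claim is verified by Monte-Carlo simulation in the
  test suite. One-sided α is the default because the alternative
  ρ > ρ₀ is directional.

## Synthetic cohorts

`generate_motion_truth` builds per-location, per-axis waveforms as sums
of 1–3 harmonics phase-locked to the cycle. The thigh-orientation-x
stream is a dominant cosine (amplitude 18–35° depending on activity,
squats deepest) whose troughs sit mid-cycle and whose flanking maxima lie
strictly inside the record (half a cycle of lead-in/out), so an
n-cycle trial yields exactly n detectable troughs and n−2 analyzed
cycles after end-discard. Jumps add an exponentially decaying 16 Hz
burst at each landing (impact transients are what make jump agreement
hardest); walking flips the sign of the x/y accelerations at the
midpoint and carries the matching direction flags. Cycle amplitudes are
modulated by a smooth per-repetition jitter (SD 2 %), a participant-level
trait (the jitter seed is drawn once per participant) so the cohort's
variance decomposition stays exact.

`render_sensor_view` maps each scalar stream through
gain·(lagged signal) + offset + N(0, σ²) — orientation distortion and
noise applied in Euler space (degrees) before quaternion conversion, so σ
is interpretable against SEM values in degrees — then composes a fixed
mounting-misalignment rotation (body frame) into the orientation and
rotates the acceleration vectors by it. Per-stream noise overrides allow
targeted perturbations of a single axis.

`generate_cohort` embeds the variance-components model: participant
effect b_i ~ N(0, σ_b²) and session effect w_ij ~ N(0, σ_w²) perturb the
outcome amplitude against a 20° reference, so ranges are linear in
b_i + w_ij and the population ICC is exactly σ_b²/(σ_b²+σ_w²). A
per-session mounting rotation of configurable SD (optionally
per-session, e.g. larger in session 3 to emulate participants attaching
their own sensors) degrades orientation outcomes the way re-placement
does in practice. The criterion device is rendered in session 1 only by
default (validity is a session-1 comparison). `simulate_range_matrix`
samples the same model directly at the outcome level; Monte-Carlo checks
of estimator recovery and CI coverage use it (500 replicates at n = 200,
1000 at n = 30 — sizes chosen to make the ±0.03 recovery and
[92 %, 98 %] coverage bands statistically meaningful), while a
single-replicate full-pipeline recovery check runs at n = 200.

**What the generator does not emulate:** soft-tissue artifact,
magnetometer disturbance, sensor fusion drift, biomechanically coupled
joint kinematics, non-Gaussian heavy-tailed noise, and non-stationary
cycle durations. Passing recovery tests therefore show the *statistical
chain* is correct, not that any particular hardware is valid.

## Numerical choices and degenerate inputs

* Recording CSVs print floats with 17 significant digits; write→read
  round-trips are exact to well below 1e−9. Quaternion norms off unit by
  ≤ 1e−3 are renormalized on read, larger deviations are integrity
  errors.
* A signal with no qualifying trough yields empty boundaries (not an
  error); ≤ 2 detected cycles leave nothing after end-discard and warn.
  Streams with zero retained cycles are omitted from the range table
  with a warning. Constant criterion waveforms and zero-variance ICC
  matrices raise informative errors.
* All simulation entry points are deterministic given their seed;
  cohort participant seeds derive as seed + participant index.
* Boundary jitter: on noisy signals the flanking maxima of a flat-topped
  thigh waveform are localized imprecisely, which misaligns paired
  cycles slightly and attenuates LFM slopes below the injected gain.
  This is a property of extremum-based segmentation itself (present in
  any such analysis), visible in the README example.

## Known limitations

* Index-based cycle pairing assumes both devices detect the same cycle
  sequence; a device dropout mid-trial would desynchronize pairs.
* The stair ascent/descent split relies on manifest labels, not
  detection.
* ICC absolute-agreement forms (ICC(A,1)) and minimal detectable change
  are intentionally not implemented.
* The Euclidean acceleration norm is computed per cycle after
  segmentation; norms of unsegmented streams are not exposed.
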