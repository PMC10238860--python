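# Methods

## Signal model and simulator

The simulator is a single-reflection tube-load model. Forward aortic flow is
an asymmetric half-sine built from two quarter-sine lobes: a sine rise over
`rise_frac · ed_ms` and a cosine fall over the remainder, so the analytic
integral is `2·A·ED/π` regardless of the rise fraction. Forward pressure is `Zc` times forward flow during
ejection; where the descending limb reaches `tail_anchor_frac` (default 0.25)
of the peak, an exponential diastolic tail with time constant `tau_decay_ms`
(default 250 ms) takes over — a pure half-sine would hand the tail a zero,
leaving no diastolic decay. The backward wave is a pure delayed, scaled copy,
`Pb(t) = γ·Pf(t − τ)`, which makes the reflection-magnitude ground truth
exactly `γ`. A biphasic incisura at end-ejection — a 20 ms negative flow lobe
(10% of peak flow) followed by a 40 ms positive rebound at 60% of that
amplitude — models the valve-closure flow oscillation; its mirrored pressure
deflections produce the dicrotic notch and the dicrotic wave whose post-notch
pressure maximum the pressure-only flow synthesis anchors on. Without the
rebound no such maximum survives measurement smoothing and the diastolic
extension of the synthesis has nothing to anchor on.

Measured pressure and flow obey `P − DBP = Pf + Pb` and `Q = (Pf − Pb)/Zc`
exactly before noise; noise is additive white Gaussian (defaults 0.5 mmHg,
2 mL/s). The forward amplitude is rescaled so that the positive-flow
integral of the *measured* flow equals the requested stroke volume — with a
reflection the backward wave subtracts flow, so scaling the forward lobe
alone would understate SV by roughly a factor (1 − γ). Recordings
concatenate beats with seeded Gaussian period jitter (SD 2% of the period)
and overlap-add each beat's diastolic tail into its successors, so the
pressure trace is continuous.

The heart-failure presets encode a rapid-pacing cardiomyopathy progression:
heart rate 86.5/99.1/120.9 bpm, stroke volume 41.2/28.0/20.8 mL, reflection
coefficient 0.48/0.39/0.38, constant characteristic impedance
0.1134 mmHg·s/mL (1.89 mmHg·min/L), shortening ejection (220/200/175 ms) and
a slowing upstroke (`rise_frac` 0.25/0.35/0.40, the contractility
surrogate that drives the falling FCW/FEW ratio). Diastolic pressure drops
75/62/60 mmHg with the failing mean pressure.

What the generator does **not** emulate: baseline wander and respiratory
modulation, ectopy and arrhythmia, re-reflection (the heart is a perfect
absorber here, except that the delayed incisura copy appears in the backward
wave), frequency-dependent damping of the reflected wave, and the
micro-morphology of real canine pulses. Tests passing on this generator
therefore demonstrate correctness of the estimators under the stated model,
not field robustness to arrhythmic or drifting telemetry.

## Preprocessing

Pressure is smoothed with a Savitzky–Golay filter (window 23 samples, order
2) followed by a zero-phase forward–backward Butterworth low-pass at 10 Hz.
The Butterworth order is configurable and defaults to 2: at order 4 the
notch-related third-derivative crossing is displaced by >150 ms on simulated
beats, while order 2 keeps it within ~25 ms of true end-ejection and still
attenuates 50 Hz by >99%.

Two smoothing tracks run in parallel. Beat detection and the normalized
ensemble waveform (landmark logic) use the full chain above; the
pressure–flow wave analyses use only the polynomial smoothing, because the
10 Hz low-pass removes the early shoulder, the incisura and the dicrotic
wave that Zc estimation, wasted-effort integrals and flow synthesis depend
on.

Systolic peaks are local maxima with prominence above a quarter of the
5th–95th percentile pressure range, separated by a refractory interval
(0.25 of the median beat period); peaks deviating more than 30% from the
moving average of the last 10 accepted peak amplitudes are rejected as
artifacts (amplitude-based plausibility; interval-based rejection is a
plausible alternative the configuration exposes indirectly via the
refractory fraction). The foot of each beat is the diastolic nadir
preceding the upstroke.

Ensembles average 8 consecutive beats. The landmark waveform resamples each
member to 500 samples and min–max normalizes before averaging (whole-beat
time normalization). The dimensional beats for WSA/WPA/synthesis are
instead signal-averaged foot-aligned on the original time grid, truncated to
the shortest member: fixed-latency features (upstroke, incisura, dicrotic
wave) stay coherent under period jitter, whereas whole-beat time
normalization maps them to different normalized positions and smears them
out of the mean. Landmark indices found on the normalized grid map onto the
signal-averaged grid through the mean member duration.

Derivatives fn′…fn⁵ are successive central differences with Savitzky–Golay
re-smoothing (window 11, order 3) between orders; repeated raw differencing
of a 500-sample waveform is numerically unusable by the fifth order.
Endpoints use one-sided stencils and are excluded from landmark logic by
construction (all landmarks are interior).

## Landmarks

The augmentation branch follows the fifth-derivative sign at peak pressure;
an exact zero counts as negative augmentation. Two practical accommodations:

* **Branch fallback.** On heavily smoothed waveforms the fifth derivative at
  a smooth peak is analytically ~0 (the generator's peak is a junction of
  raised-cosine pieces) and its numerical sign tracks global hump asymmetry
  rather than augmentation class. A branch whose construction is
  self-contradictory — the required fourth-derivative crossing is absent or
  mis-ordered — therefore falls back to the other branch; only if both fail
  is the beat excluded (counted, never imputed). On simulated beats the
  negative-augmentation construction is the one that typically succeeds,
  which puts P1 at the pressure maximum; `tr_ms` then measures foot-to-peak
  rather than foot-to-shoulder. This is a known limitation of applying the
  fifth-derivative heuristic to tube-load composites; the selection logic
  itself is unit-tested against analytically constructed derivative arrays
  and an independent spline oracle.
* **Notch bias.** The dicrotic notch is the first positive-to-negative
  third-derivative crossing after peak pressure. On the 10 Hz-filtered
  waveform this lands systematically ~20–25 ms after the generated incisura
  trough (smoothing bias). All integral windows inherit this small bias; it
  is consistent across beats and stages and does not affect the
  directional results.

Wasted effort uses P1 as the inflection for positive augmentation and P2 for
negative augmentation (the published definition leaves the negative case
open); when P2 falls past the notch the reflected systolic area is empty and
E_w = 0. Zero crossings are located by sign change with linear sub-sample
interpolation; exact zeros attach to the left interval. Areas are
trapezoidal in mmHg·ms; negative areas beyond −1e−9 of scale raise an
internal-consistency error, smaller ones clamp to zero.

## Wave separation, wave power, synthetic flow

Zc comes from the time-domain early-systolic loop slope over the flow
upstroke from 5% to 50% of peak flow (a fixed-duration 60 ms window mode is
available). On noise-free simulated beats the estimate is exact to machine
precision, including with a γ = 0.48 reflection, because the reflection
(τ = 50–60 ms) arrives after the fit window closes (~27 ms). Per-beat Zc
values are estimated on each ensemble beat and averaged per session.

Wave power uses per-sample differences of lightly smoothed pressure and flow
on a canonical 500 Hz grid (recordings at other rates are resampled first so
magnitudes are comparable), scaled to µW. Classification windows anchor to
landmarks: FCW in [foot, pressure peak], FEW in [peak, DN + 20 ms], BCW in
[foot, DN]. An absent BCW is a normal finding; an absent FCW flags the beat.

Synthetic flow implements the concordance-plus-ramp construction described
above with no free parameters: the ramp rises linearly from zero at the
inflection anchor (P1 for positive augmentation; P2, or P1 when P2 falls
past the notch, for negative augmentation) to the diastole-zeroed notch
pressure at DN and is held constant through the post-notch diastolic
maximum. The early-systole gain is identity — flow scaling is immaterial
because an effective impedance is refit on the synthetic flow by the same
slope rule, making every reported index invariant to rescaling (verified to
1e−9). Because the simulator's landmark branch anchors late (at the
pressure peak rather than an early shoulder), the synthetic waveform peaks
~80 ms after true flow; its rank concordance with true flow over systole is
~0.6 rather than the ~0.9 achievable with an early anchor. Session-level
reflection-magnitude concordance between synthetic- and measured-flow
computations remains high (Spearman ≥ 0.93 across seeds on a γ sweep of
0.10–0.60, 24-beat sessions), which is the property the method is used for.

## Agreement statistics and problem sizes

Bland–Altman bias and 95% limits of agreement use the sample (n−1) standard
deviation and ±1.96·SD; Spearman's rho uses average ranks and is reported
missing when undefined (n < 3 or zero rank variance). Repeated-measures
ANOVA is out of scope.

The validation suite runs at desk scale: 8-beat recordings for
ground-truth recovery (50 noisy replicates for the reflection-magnitude
bound), 24-beat sessions (3 ensemble groups) per condition for the
concordance sweep (11 γ levels) and the three-stage progression suite, and a
40-beat session for the pipeline contract. These sizes give stable session
means while keeping the full suite in a few seconds.

## Known limitations

* The fifth-derivative augmentation heuristic is morphology-sensitive; on
  tube-load composites it effectively always selects the
  negative-augmentation construction (see Landmarks). Absolute Tr/Ap values
  from simulated sessions should be read with that in mind.
* Synthetic-flow absolute index values differ from measured-flow values by
  wide margins (QZc roughly double, wasted effort a fraction); only
  directions and rank agreement are validated, mirroring how the method is
  used.
* The reader ingests delimited text only; physiologic binary formats are an
  extension point.
* Flow-unit declaration is mandatory for non-canonical columns — the probe's
  native unit cannot be guessed safely.
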