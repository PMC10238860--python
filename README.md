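# pulsewave

Pulsatile arterial hemodynamics from pressure–flow waveforms: pulse wave
analysis (PWA), wave separation analysis (WSA) and wave power analysis (WPA)
for continuous aortic recordings, plus a pressure-only synthetic-flow mode
for settings where an aortic flow probe is unavailable. The package targets
preclinical (large-animal telemetry) waveforms — conscious-canine aortic
pressure at 500 Hz is the reference use case — and ships a tube-load
simulator that generates paired pressure–flow recordings with exact ground
truth, so every estimator can be validated against known generative
parameters.

## What it computes

**PWA** — beats are detected on a smoothed pressure trace (Savitzky–Golay,
window 23 / order 2, then a zero-phase 10 Hz low-pass), grouped into
ensembles of 8 consecutive beats, amplitude- and time-normalized, and
averaged. On the mean waveform *fn*, landmarks are located from the signs
and zero crossings of its first through fifth finite-difference derivatives:
with positive augmentation (fn⁵ < 0 at peak pressure) the late systolic peak
P2 is the pressure maximum and the early shoulder P1 is the second
positive-to-negative crossing of fn⁴ after the steepest upstroke; with
negative augmentation P1 is the maximum and P2 the first
negative-to-positive fn⁴ crossing after it; the dicrotic notch (DN) is the
first positive-to-negative crossing of fn‴ after peak pressure. Per-beat
indices follow: augmented pressure Ap = P(P2) − P(P1), ejection duration
ED = Tr + SDR (foot→P1 and P1→DN times), wasted effort E_w (systolic area of
the reflected wave above the inflection point), pressure systolic area
PSA (area above diastolic pressure left of DN, minus E_w — a stroke-volume
surrogate), SPTI = ΔSPTI + PSA + E_w, and DPTI.

**WSA** — characteristic impedance Zc is the least-squares slope of the
early-systolic pressure–flow loop (flow rising from 5% to 50% of its peak).
With diastole-zeroed pressure P and flow Q,

    Pf = (P + Q·Zc) / 2        Pb = (P − Q·Zc) / 2

so Pf + Pb reconstructs P exactly. Reflection magnitude RM = Pb/Pf amplitude
ratio; QZc is the systolic time integral of Q·Zc (mmHg·ms); wasted pressure
effort is the systolic excess of P over Q·Zc; wasted effort/QZc is their
dimensionless ratio.

**WPA** — wave power dΠ = dP·dQ per sample on a canonical 500 Hz grid
(1 mmHg·mL/s = 133.322 µW), classified by sign patterns: forward compression
wave FCW (+dΠ, +dP, +dQ, early systole), forward expansion wave FEW
(+dΠ, −dP, −dQ, late systole), backward compression wave BCW
(−dΠ, +dP, −dQ, mid systole; normally absent without reflection).

**Synthetic flow** — an uncalibrated flow waveform built from the pressure
beat alone: flow tracks diastole-zeroed pressure up to the inflection point,
then a quasi-linear reflected-wave ramp (zero at the inflection, equal to
the notch pressure at DN, constant afterwards) is subtracted through the
post-notch diastolic pressure maximum, reproducing the brief diastolic flow
reversal. Only flow-scale-invariant indices are reported from it (Pf, Pb,
RM, QZc, wasted effort, wasted effort/QZc, FCW/FEW height ratio); absolute
Zc and absolute FCW/FEW heights are suppressed. Agreement between
measured-flow and synthetic-flow indices is quantified with Bland–Altman
bias / 95% limits of agreement and Spearman's rho.

## Worked example

Simulate a 24-beat conscious-canine baseline recording (heart rate
86.5 bpm, stroke volume 41.2 mL, reflection coefficient 0.48, Zc
1.89 mmHg·min/L) and analyze it:

```sh
pulsewave simulate --preset baseline --beats 24 --seed 7 --out demo.csv
pulsewave analyze demo.csv --out demo_report.csv
```

`demo_report.csv` contains one row per 8-beat ensemble group and flow
source, plus session means (columns abridged):

```
         row flow_source    hr   ed_ms      psa  zc_mmhg_min_per_l  pf_amp  pb_amp    rm  qzc_int  fcw_few_ratio  sv_ml
     group_0    measured 87.06  242.50  8828.19              1.859  43.702  21.144 0.484  3824.15          8.845 41.721
     group_0   synthetic 87.06  242.50  8828.19                    58.314  11.008 0.189  7960.64          2.583
     ...
session_mean    measured 86.97  244.58  8825.41              1.868  44.600  21.430 0.481  3850.68          9.197 42.108
session_mean   synthetic 86.97  244.58  8825.41                    59.499  10.920 0.184  8042.41          2.966
```

The measured-flow session means recover the generative truth: RM 0.481
against a reflection coefficient of 0.48, Zc 1.868 against 1.89 mmHg·min/L,
stroke volume 42.1 against 41.2 mL. The synthetic-flow rows report only the
flow-scale-invariant subset (blank Zc and SV by design); their absolute
values differ from the measured-flow ones — as expected for an uncalibrated
waveform — but track them across conditions, which is what
`demo_report.agreement.csv` (Bland–Altman bias, 95% limits of agreement,
Spearman's rho per index) quantifies.

Heart-failure progression presets (`baseline`, `week1`, `month1`) emulate
chronic rapid-pacing cardiomyopathy: stroke volume 41.2 → 28.0 → 20.8 mL,
heart rate 86.5 → 99.1 → 120.9 bpm, reflection falling while Zc stays
constant. `pulsewave compare a.csv b.csv c.csv --out agreement.csv` pools
ensemble rows across sessions and reports per-session means alongside the
measured-vs-synthetic agreement block, reproducing the qualitative
signature: SV, PSA, Pf, Pb, QZc, wasted effort and the FCW/FEW ratio all
fall monotonically while Zc is unchanged.

The same API is available from Python:

```python
from pulsewave import hf_preset, simulate_recording, analyze_recording

rec = simulate_recording(hf_preset("baseline", seed=7), n_beats=24)
report = analyze_recording(rec)
print(report.summary[["rm", "zc_mmhg_min_per_l", "sv_ml", "psa"]])
```

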