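"""Paired aortic pressure--flow simulator (tube-load, single reflection).

The generative model is a forward wave plus one delayed, scaled reflection:

* forward aortic flow is an asymmetric half-sine over the ejection duration
  (quarter-sine rise over ``rise_frac * ed_ms``, quarter-sine fall over the
  remainder), whose analytic integral is ``2 A ED / pi`` regardless of the
  rise fraction;
* forward pressure is ``Zc`` times the forward flow during ejection, handed
  over to an exponential diastolic tail (time constant ``tau_decay_ms``)
  where the descending limb falls to ``tail_anchor_frac`` of the peak;
* the backward wave is a pure delayed, scaled copy,
  ``Pb(t) = gamma * Pf(t - tau)``, so the reflection magnitude ground truth
  is exactly ``gamma``;
* a brief raised-cosine negative flow lobe at end-ejection (the incisura)
  carries its mirrored pressure deflection, guaranteeing a dicrotic notch;
* measured pressure and flow follow the exact identities
  ``P - DBP = Pf + Pb`` and ``Q = (Pf - Pb) / Zc`` before noise.

The forward amplitude is scaled so the positive-flow integral of the
*measured* flow equals the requested stroke volume, so SV ground truth holds
for any reflection coefficient. Heart-failure progression presets
(``baseline``, ``week1``, ``month1``) emulate a rapid-ventricular-pacing
study arm: stroke volume and reflection fall while heart rate rises and
characteristic impedance stays fixed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .waveform_io import Recording

__all__ = [
    "SimParams",
    "PairedBeat",
    "simulate_beat",
    "simulate_recording",
    "hf_preset",
    "PRESET_STAGES",
]


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of one simulated subject/session.

    Units: ``zc_true`` mmHg*s/mL, times ms, ``sv_ml`` mL, pressures mmHg,
    noise SDs mmHg and mL/s, ``fs_hz`` Hz. ``gamma`` is the reflection
    coefficient in [0, 1); ``tau_ms`` the round-trip reflection delay;
    ``rise_frac`` the fraction of ejection spent on the flow upstroke
    (contractility surrogate); ``tail_anchor_frac`` where on the descending
    limb the exponential diastolic tail takes over.
    """

    zc_true: float = 0.1134
    gamma: float = 0.48
    tau_ms: float = 60.0
    hr_bpm: float = 86.5
    ed_ms: float = 220.0
    sv_ml: float = 41.2
    dbp_mmhg: float = 72.0
    tau_decay_ms: float = 250.0
    noise_sd_mmhg: float = 0.5
    noise_sd_flow: float = 2.0
    fs_hz: float = 500.0
    seed: int = 0
    rise_frac: float = 0.25
    tail_anchor_frac: float = 0.25
    incisura_ms: float = 20.0
    incisura_frac: float = 0.10
    rebound_frac: float = 0.6
    rebound_ms: float = 40.0
    jitter_frac: float = 0.02

    @property
    def period_ms(self) -> float:
        return 60000.0 / self.hr_bpm

    def validate(self) -> None:
        if not 0.0 <= self.gamma < 1.0:
            raise ParameterError("gamma must satisfy 0 <= gamma < 1")
        for name in ("zc_true", "hr_bpm", "ed_ms", "sv_ml", "dbp_mmhg",
                     "tau_decay_ms", "fs_hz"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        for name in ("noise_sd_mmhg", "noise_sd_flow", "tau_ms"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.ed_ms >= self.period_ms:
            raise ParameterError("ed_ms must be shorter than the beat period")
        if self.tau_ms >= self.ed_ms:
            raise ParameterError("tau_ms must be shorter than ed_ms")
        if not 0.0 < self.rise_frac < 1.0:
            raise ParameterError("rise_frac must lie in (0, 1)")
        if not 0.0 < self.tail_anchor_frac < 1.0:
            raise ParameterError("tail_anchor_frac must lie in (0, 1)")

    def replace(self, **kwargs) -> "SimParams":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PairedBeat:
    """One simulated beat with exact generative ground truth.

    ``p - dbp == pf_true + pb_true`` and ``q == (pf_true - pb_true)/zc``
    hold at every sample before the stored noise was added.
    """

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    truth: SimParams
    pf_true: np.ndarray
    pb_true: np.ndarray


def _forward_shape(t_s: np.ndarray, params: SimParams) -> np.ndarray:
    """Unit-peak forward flow shape: asymmetric half-sine + tail + incisura.

    ``t_s`` may extend past the beat period; the exponential tail continues,
    which lets a recording carry each beat's diastolic tail into the next.
    """
    ed = params.ed_ms / 1000.0
    rise = params.rise_frac * ed
    fall = ed - rise
    shape = np.zeros_like(t_s)

    up = (t_s >= 0) & (t_s < rise)
    shape[up] = np.sin(0.5 * np.pi * t_s[up] / rise)
    down = (t_s >= rise) & (t_s <= ed)
    shape[down] = np.cos(0.5 * np.pi * (t_s[down] - rise) / fall)

    # Exponential diastolic tail anchored where the descending limb reaches
    # tail_anchor_frac of the peak; a half-sine alone would hand over a zero.
    frac = params.tail_anchor_frac
    t_anchor = rise + (2.0 * fall / np.pi) * np.arccos(frac)
    tail = t_s > t_anchor
    shape[tail] = frac * np.exp(-(t_s[tail] - t_anchor)
                                / (params.tau_decay_ms / 1000.0))

    # Biphasic incisura centred at end-ejection: a brief negative flow lobe
    # (valve closure backflow) followed by a slower positive rebound. Their
    # mirrored pressure deflections form the dicrotic notch and the dicrotic
    # wave -- the post-notch diastolic pressure maximum that pressure-only
    # flow synthesis anchors on.
    w = params.incisura_ms / 1000.0
    if w > 0 and params.incisura_frac > 0:
        inc = (t_s >= ed - 0.5 * w) & (t_s <= ed + 0.5 * w)
        phase = (t_s[inc] - (ed - 0.5 * w)) / w
        shape[inc] -= params.incisura_frac * 0.5 * (1 - np.cos(2 * np.pi * phase))
        wr = params.rebound_ms / 1000.0
        if wr > 0 and params.rebound_frac > 0:
            reb = (t_s > ed + 0.5 * w) & (t_s <= ed + 0.5 * w + wr)
            phase_r = (t_s[reb] - (ed + 0.5 * w)) / wr
            shape[reb] += (params.rebound_frac * params.incisura_frac
                           * 0.5 * (1 - np.cos(2 * np.pi * phase_r)))
    return shape


def _components(n: int, params: SimParams, n_total: int | None = None):
    """Noise-free forward/backward pressure and flow over ``n_total`` samples.

    The beat occupies the first ``n`` samples; anything beyond is the
    carried-over diastolic tail. Returns (pf, pb, q) with the forward
    amplitude scaled so the positive-flow integral over the *beat* equals
    ``sv_ml``.
    """
    if n_total is None:
        n_total = n
    t = np.arange(n_total) / params.fs_hz
    fwd = _forward_shape(t, params)
    delay = int(round(params.tau_ms / 1000.0 * params.fs_hz))
    bwd = np.zeros_like(fwd)
    if params.gamma > 0:
        bwd[delay:] = params.gamma * fwd[: n_total - delay]
    q_unit = fwd - bwd
    sv_unit = np.trapezoid(np.maximum(q_unit[:n], 0.0), dx=1.0 / params.fs_hz)
    amp = params.sv_ml / sv_unit  # peak forward flow, mL/s
    pf = params.zc_true * amp * fwd
    pb = params.zc_true * amp * bwd
    q = amp * q_unit
    return pf, pb, q


def simulate_beat(params: SimParams) -> PairedBeat:
    """Generate one paired pressure--flow beat with exact ground truth."""
    params.validate()
    fs = params.fs_hz
    n = int(round(params.period_ms / 1000.0 * fs))
    pf, pb, q = _components(n, params)
    t = np.arange(n) / fs
    rng = np.random.default_rng(params.seed)
    p = params.dbp_mmhg + pf + pb
    if params.noise_sd_mmhg > 0:
        p = p + rng.normal(0.0, params.noise_sd_mmhg, n)
    q_noisy = q
    if params.noise_sd_flow > 0:
        q_noisy = q + rng.normal(0.0, params.noise_sd_flow, n)
    return PairedBeat(t=t, p=p, q=q_noisy, truth=params, pf_true=pf, pb_true=pb)


def simulate_recording(params: SimParams, n_beats: int) -> Recording:
    """Concatenate ``n_beats`` beats with seeded period jitter.

    Each beat's diastolic tail is overlap-added into the following beats, so
    the pressure trace is continuous. The true beat-onset sample indices and
    the generative parameters are stored in ``Recording.meta``.
    """
    params.validate()
    if n_beats < 1:
        raise ParameterError("n_beats must be >= 1")
    fs = params.fs_hz
    rng = np.random.default_rng(params.seed)
    base_n = params.period_ms / 1000.0 * fs
    jitter = rng.normal(0.0, params.jitter_frac, n_beats).clip(-0.1, 0.1)
    lengths = np.maximum(np.round(base_n * (1.0 + jitter)).astype(int),
                         int(np.ceil(params.ed_ms / 1000.0 * fs)) + 2)
    onsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    total = int(lengths.sum())

    p = np.full(total, params.dbp_mmhg)
    q = np.zeros(total)
    for onset, n_i in zip(onsets, lengths):
        n_ext = min(total - onset, int(n_i) + 3 * int(round(base_n)))
        pf, pb, qb = _components(int(n_i), params, n_total=n_ext)
        p[onset:onset + n_ext] += pf + pb
        q[onset:onset + n_ext] += qb
    if params.noise_sd_mmhg > 0:
        p = p + rng.normal(0.0, params.noise_sd_mmhg, total)
    if params.noise_sd_flow > 0:
        q = q + rng.normal(0.0, params.noise_sd_flow, total)

    meta = {
        "truth": params.as_dict(),
        "onsets": onsets.tolist(),
        "beat_lengths": lengths.tolist(),
        "n_beats": n_beats,
    }
    return Recording(t=np.arange(total) / fs, p=p, q=q, fs_hz=fs, meta=meta)


# Rapid-pacing heart-failure progression: HR and SV from the study's
# hemodynamic table (86.5/99.1/120.9 bpm; 41.2/28.0/20.8 mL), reflection
# coefficient from the measured reflection magnitudes (0.48/0.39/0.38),
# characteristic impedance held constant (1.89 mmHg*min/L = 0.1134 mmHg*s/mL;
# unchanged by pacing). Ejection shortens and the upstroke slows (rise_frac
# up) as contractility falls; DBP drops with the reported MAP decline.
PRESET_STAGES = ("baseline", "week1", "month1")

_PRESETS = {
    "baseline": dict(hr_bpm=86.5, sv_ml=41.2, gamma=0.48, dbp_mmhg=75.0,
                     ed_ms=220.0, tau_ms=60.0, rise_frac=0.25),
    "week1": dict(hr_bpm=99.1, sv_ml=28.0, gamma=0.39, dbp_mmhg=62.0,
                  ed_ms=200.0, tau_ms=55.0, rise_frac=0.35),
    "month1": dict(hr_bpm=120.9, sv_ml=20.8, gamma=0.38, dbp_mmhg=60.0,
                   ed_ms=175.0, tau_ms=50.0, rise_frac=0.40),
}


def hf_preset(stage: str, **overrides) -> SimParams:
    """Return the simulation parameters for one heart-failure stage.

    ``stage`` is one of ``baseline``, ``week1``, ``month1``. Keyword
    overrides (e.g. ``seed=7``, ``noise_sd_mmhg=0``) are applied on top.
    """
    if stage not in _PRESETS:
        raise ParameterError(
            f"unknown stage {stage!r}; valid stages: {list(PRESET_STAGES)}"
        )
    params = SimParams(zc_true=0.1134, **_PRESETS[stage]).replace(**overrides)
    params.validate()
    return params
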