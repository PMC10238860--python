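"""Pressure-only ("personalized") synthetic flow.

An uncalibrated aortic flow waveform is synthesized from a single pressure
beat using established pressure--flow principles: pressure and flow rise
concordantly until the early inflection point; in mid-to-late systole a
lower-frequency reflected wave with a quasi-linear upstroke adds to forward
pressure, so subtracting a linear ramp (zero at the inflection point, equal
to the diastole-zeroed notch pressure at the dicrotic notch) recovers the
flow's parallel late-systolic decay and forces zero flow at end-ejection.
Extending the subtraction -- ramp held constant -- through the post-notch
diastolic pressure maximum reproduces the brief early-diastolic flow
reversal; flow is zero thereafter. Flow scaling is immaterial for the
indices this waveform feeds (principle: wave separation ratios and
pressure--time integrals are invariant to the flow unit), so the early
concordance uses the identity gain.

Only flow-scale-invariant indices are reported from synthetic flow:
forward/backward pressures and amplitudes, reflection magnitude, QZc, wasted
effort and their ratio (all pressure--time quantities once the effective
impedance is refit on the synthetic flow itself), and the FCW/FEW height
ratio. Absolute impedance and absolute wave-power heights are suppressed --
they are not derivable from uncalibrated flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .errors import SynthesisError
from .pwa import PwaLandmarks
from .wpa import classify_waves, wave_power
from .wsa import WsaResult, estimate_zc, separate_waves, wasted_effort_indices

__all__ = ["SyntheticFlowBeat", "SyntheticIndices",
           "synthesize_flow", "wsa_wpa_from_synthetic"]

_DEFAULT = AnalysisConfig()


@dataclass
class SyntheticFlowBeat:
    """Uncalibrated synthetic flow on the same grid as its pressure beat."""

    qs: np.ndarray
    p1_idx: int
    dn_idx: int
    dpeak_idx: int
    ramp: np.ndarray
    uncalibrated: bool = True


@dataclass
class SyntheticIndices:
    """Flow-scale-invariant index subset derived from synthetic flow.

    Absolute Zc and absolute FCW/FEW heights are deliberately absent.
    """

    pf: np.ndarray
    pb: np.ndarray
    pf_amp: float
    pb_amp: float
    rm: float
    qzc_int: float
    wasted_effort: float
    wasted_ratio: float
    fcw_few_ratio: float | None
    flow_source: str = "synthetic"


def synthesize_flow(
    p_beat: np.ndarray,
    landmarks: PwaLandmarks,
    fs_hz: float,
) -> SyntheticFlowBeat:
    """Synthesize an uncalibrated flow waveform from one pressure beat.

    ``landmarks`` must be valid and expressed as sample indices on
    ``p_beat``'s grid (foot at sample 0). For beats with negative
    augmentation (P1 at the pressure peak) the ramp is anchored at P2
    instead.
    """
    p_beat = np.asarray(p_beat, dtype=float)
    if not landmarks.valid:
        raise SynthesisError(f"invalid landmarks: {landmarks.reason or 'unset'}")
    dn = landmarks.dn_idx
    if not 0 < dn < p_beat.size - 2:
        raise SynthesisError("dicrotic notch missing or at the beat edge")
    if landmarks.augmentation_sign == "positive":
        anchor = landmarks.p1_idx
    else:
        # Negatively augmented beat: anchor at P2 when it precedes the notch,
        # else at the pressure peak (P1) -- P2 may land past end-ejection.
        anchor = landmarks.p2_idx if landmarks.p2_idx < dn else landmarks.p1_idx
    if not 0 <= anchor < dn:
        raise SynthesisError("inflection anchor not before the dicrotic notch")

    ps = p_beat - p_beat.min()

    # Post-notch diastolic pressure maximum (end of the synthesized span).
    after = ps[dn + 1:]
    rel = _first_local_max(after)
    if rel is None:
        raise SynthesisError("no post-notch diastolic pressure maximum")
    dpeak = dn + 1 + rel

    ramp = np.zeros_like(ps)
    ramp[anchor:dn + 1] = np.linspace(0.0, ps[dn], dn - anchor + 1)
    ramp[dn + 1:] = ps[dn]

    qs = np.zeros_like(ps)
    qs[:anchor + 1] = ps[:anchor + 1]
    qs[anchor + 1:dpeak + 1] = ps[anchor + 1:dpeak + 1] - ramp[anchor + 1:dpeak + 1]
    # qs is identically zero after the diastolic maximum.
    return SyntheticFlowBeat(qs=qs, p1_idx=landmarks.p1_idx, dn_idx=dn,
                             dpeak_idx=dpeak, ramp=ramp)


def _first_local_max(x: np.ndarray) -> int | None:
    """Index of the first strict-then-flat local maximum of ``x``."""
    if x.size < 3:
        return None
    for i in range(1, x.size - 1):
        if x[i] >= x[i - 1] and x[i] > x[i + 1]:
            return i
    return None


def wsa_wpa_from_synthetic(
    p_beat: np.ndarray,
    qs: np.ndarray,
    landmarks: PwaLandmarks,
    fs_hz: float,
    config: AnalysisConfig = _DEFAULT,
) -> SyntheticIndices:
    """Wave separation and wave power restricted to flow-scale-free indices.

    An effective impedance is refit on (pressure, synthetic flow) with the
    same early-systolic slope rule used for measured flow; because the
    synthetic flow equals diastole-zeroed pressure in early systole, that
    slope is near unity in scaled units, and every reported quantity is
    invariant to any rescaling of ``qs``.
    """
    p_beat = np.asarray(p_beat, dtype=float)
    qs = np.asarray(qs, dtype=float)
    fit = estimate_zc(p_beat, qs, fs_hz, config)
    sep: WsaResult = separate_waves(p_beat, qs, fit.zc, fit)
    qzc_int, wasted, ratio = wasted_effort_indices(
        p_beat, qs, fit.zc, landmarks.dn_idx, fs_hz)

    dpi, dP, dQ, fs_grid = wave_power(p_beat, qs, fs_hz, config)
    scale = fs_grid / fs_hz
    ppeak = int(round(np.argmax(p_beat) * scale))
    dn = int(round(landmarks.dn_idx * scale))
    wpa = classify_waves(dpi, dP, dQ, ppeak, dn, fs_grid, config)

    return SyntheticIndices(
        pf=sep.pf, pb=sep.pb, pf_amp=sep.pf_amp, pb_amp=sep.pb_amp, rm=sep.rm,
        qzc_int=qzc_int, wasted_effort=wasted, wasted_ratio=ratio,
        fcw_few_ratio=wpa.fcw_few_ratio,
    )
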