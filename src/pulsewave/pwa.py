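"""Pulse wave analysis: landmark location and pressure--time indices.

Landmarks are found on the normalized ensemble waveform via the sign of the
fifth derivative at peak pressure: a negative fifth derivative marks positive
augmentation (the late systolic peak P2 is the pressure maximum, and the
early shoulder P1 is the second positive-to-negative zero crossing of the
fourth derivative after the maximum upstroke slope); a positive one marks
negative augmentation (P1 is the maximum, and P2 the first
negative-to-positive fourth-derivative crossing after it). The dicrotic
notch is the first positive-to-negative third-derivative crossing after peak
pressure. Indices (augmented pressure, ejection/reflection timings, and the
systolic/diastolic pressure--time areas) are then computed per member beat in
native mmHg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np

from .errors import AggregationError, InternalConsistencyError
from .preprocess import EnsembleBeat

__all__ = [
    "PwaLandmarks",
    "PwaIndices",
    "locate_landmarks",
    "compute_pwa_indices",
    "aggregate_session",
    "zero_crossings",
]

logger = logging.getLogger(__name__)

#: Negative area below this magnitude (mmHg*ms) is clamped to zero.
_AREA_TOL = 1e-9


@dataclass
class PwaLandmarks:
    """P1 / P2 / dicrotic-notch positions on the normalized ensemble grid."""

    p1_idx: int = -1
    p2_idx: int = -1
    dn_idx: int = -1
    augmentation_sign: str = ""
    valid: bool = False
    reason: str = ""


@dataclass
class PwaIndices:
    """Per-beat pulse-wave indices (pressures mmHg, times ms, areas mmHg*ms).

    Invariants (up to integration round-off): ``ed_ms == tr_ms + sdr_ms``
    and ``spti == delta_spti + psa + ew``.
    """

    sbp: float
    dbp: float
    map: float
    hr: float
    ap: float
    ed_ms: float
    tr_ms: float
    sdr_ms: float
    ew: float
    psa: float
    spti: float
    delta_spti: float
    dpti: float


def zero_crossings(d: np.ndarray, direction: str, start: int = 0) -> list[float]:
    """Indices where ``d`` crosses zero in the given direction after ``start``.

    ``direction`` is ``"down"`` (positive to negative) or ``"up"``. Crossing
    positions are refined by linear sub-sample interpolation; an exact zero
    attaches to the interval on its left.
    """
    d = np.asarray(d, dtype=float)
    sign = np.sign(d)
    out: list[float] = []
    for i in range(max(start, 0), d.size - 1):
        a, b = sign[i], sign[i + 1]
        if direction == "down":
            hit = a > 0 and b <= 0
        elif direction == "up":
            hit = a < 0 and b >= 0
        else:
            raise ValueError("direction must be 'up' or 'down'")
        if hit:
            denom = d[i] - d[i + 1]
            frac = d[i] / denom if denom != 0 else 0.0
            out.append(i + float(frac))
    return out


def _try_positive(ens: EnsembleBeat, peak: int) -> tuple[int, int] | str:
    """Positive-augmentation construction: P2 at the maximum, P1 at the
    second +/- fourth-derivative crossing after the maximum upstroke slope."""
    upstroke = int(np.argmax(ens.d1))
    downs = zero_crossings(ens.d4, "down", start=upstroke)
    if len(downs) < 2:
        return "second down-crossing of fourth derivative not found"
    p1 = int(round(downs[1]))
    if not p1 < peak:
        return "early shoulder did not precede late systolic peak"
    return p1, peak


def _try_negative(ens: EnsembleBeat, peak: int) -> tuple[int, int] | str:
    """Negative-augmentation construction: P1 at the maximum, P2 at the first
    -/+ fourth-derivative crossing after it."""
    ups = zero_crossings(ens.d4, "up", start=peak)
    if not ups:
        return "up-crossing of fourth derivative after P1 not found"
    return peak, int(round(ups[0]))


def locate_landmarks(ens: EnsembleBeat) -> PwaLandmarks:
    """Locate P1, P2 and the dicrotic notch on an ensemble waveform.

    The branch is chosen by the sign of the fifth derivative at peak
    pressure (an exact zero counts as negative augmentation). Because that
    sign is numerically fragile on heavily smoothed waveforms, a branch whose
    construction is self-contradictory (its required fourth-derivative
    crossing is absent or mis-ordered) falls back to the other branch; only
    when both constructions fail is the beat flagged invalid with a reason
    and excluded downstream -- never silently filled.
    """
    fn = ens.fn
    peak = int(np.argmax(fn))
    lm = PwaLandmarks()
    d5_at_peak = ens.d5[peak]
    if d5_at_peak == 0.0:
        logger.info("fifth derivative exactly zero at peak; treating as "
                    "negative augmentation")

    order = (("positive", _try_positive), ("negative", _try_negative))
    if d5_at_peak >= 0:
        order = order[::-1]
    reasons = []
    for sign, attempt in order:
        got = attempt(ens, peak)
        if isinstance(got, tuple):
            lm.augmentation_sign = sign
            lm.p1_idx, lm.p2_idx = got
            break
        reasons.append(f"{sign}: {got}")
    else:
        lm.reason = "; ".join(reasons)
        return lm
    if reasons:
        logger.info("augmentation branch reclassified as %s (%s)",
                    lm.augmentation_sign, reasons[0])

    notches = zero_crossings(ens.d3, "down", start=peak)
    if not notches:
        lm.reason = "third-derivative down-crossing (dicrotic notch) not found"
        return lm
    lm.dn_idx = int(round(notches[0]))
    # P2 of a negatively augmented beat may fall past the notch; the wasted
    # effort integral is then empty, which is handled downstream.
    if not (0 <= lm.p1_idx < lm.dn_idx < ens.n - 1 and 0 <= lm.p2_idx < ens.n):
        lm.reason = "landmarks out of order within the beat"
        return lm
    lm.valid = True
    return lm


def _area(y: np.ndarray, dt_ms: float, what: str) -> float:
    a = float(np.trapezoid(y, dx=dt_ms))
    if a < -_AREA_TOL * max(1.0, float(np.abs(y).max()) * dt_ms * y.size):
        raise InternalConsistencyError(f"negative {what} area: {a}")
    return max(a, 0.0)


def compute_pwa_indices(
    p_seg: np.ndarray,
    p1_idx: int,
    p2_idx: int,
    dn_idx: int,
    fs_hz: float,
    augmentation_sign: str = "positive",
) -> PwaIndices:
    """Compute the pulse-wave indices of one member beat.

    ``p_seg`` is the beat's pressure in mmHg from foot to next foot;
    landmark indices are sample offsets within it. Areas use trapezoidal
    integration in mmHg*ms; diastolic pressure is taken at the foot.
    """
    p_seg = np.asarray(p_seg, dtype=float)
    dt_ms = 1000.0 / fs_hz
    dbp = float(p_seg[0])
    sbp = float(p_seg.max())

    ap = float(p_seg[p2_idx] - p_seg[p1_idx])
    ed_ms = dn_idx * dt_ms
    tr_ms = p1_idx * dt_ms
    sdr_ms = (dn_idx - p1_idx) * dt_ms

    infl = p1_idx if augmentation_sign == "positive" else p2_idx
    if infl < dn_idx:
        seg = p_seg[infl:dn_idx + 1]
        ew = _area(np.maximum(seg - p_seg[infl], 0.0), dt_ms, "wasted-effort")
    else:
        ew = 0.0  # inflection past the notch: no reflected systolic area
    spti = _area(p_seg[:dn_idx + 1], dt_ms, "systolic pressure-time")
    psa = _area(p_seg[:dn_idx + 1] - dbp, dt_ms, "pressure systolic") - ew
    if psa < -_AREA_TOL * max(spti, 1.0):
        raise InternalConsistencyError("wasted effort exceeds systolic area")
    psa = max(psa, 0.0)
    delta_spti = spti - psa - ew
    dpti = _area(p_seg[dn_idx:], dt_ms, "diastolic pressure-time")

    return PwaIndices(
        sbp=sbp, dbp=dbp, map=float(p_seg.mean()),
        hr=60.0 * fs_hz / p_seg.size,
        ap=ap, ed_ms=ed_ms, tr_ms=tr_ms, sdr_ms=sdr_ms,
        ew=ew, psa=psa, spti=spti, delta_spti=delta_spti, dpti=dpti,
    )


def indices_for_ensemble(
    ens: EnsembleBeat, lm: PwaLandmarks, p: np.ndarray, fs_hz: float
) -> list[PwaIndices]:
    """Map ensemble landmarks back to each member beat and compute indices."""
    out: list[PwaIndices] = []
    for j, seg in enumerate(ens.member_beats):
        p1 = ens.member_index(j, lm.p1_idx)
        p2 = ens.member_index(j, lm.p2_idx)
        dn = ens.member_index(j, lm.dn_idx)
        p_beat = np.asarray(p[seg.onset_idx:seg.end_idx + 1], dtype=float)
        ordered = 0 <= p1 < dn < p_beat.size and 0 <= p2 < p_beat.size
        if not ordered:
            continue
        out.append(compute_pwa_indices(
            p_beat, p1, p2, dn, fs_hz, lm.augmentation_sign))
    return out


def aggregate_session(per_beat: list[PwaIndices], n_excluded: int = 0) -> dict:
    """Arithmetic mean and SD of every index across valid beats."""
    if not per_beat:
        raise AggregationError("no valid beats to aggregate")
    out: dict = {"n_beats": len(per_beat), "n_excluded": n_excluded}
    for f in fields(PwaIndices):
        vals = np.array([getattr(b, f.name) for b in per_beat], dtype=float)
        out[f"{f.name}_mean"] = float(vals.mean())
        out[f"{f.name}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if any(not math.isfinite(v) for v in out.values()):
        raise AggregationError("non-finite aggregate index")
    return out
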