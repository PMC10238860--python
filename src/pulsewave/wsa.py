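"""Wave separation analysis.

Characteristic impedance Zc is the least-squares slope of the early-systolic
pressure--flow relationship (flow rising from 5% to 50% of its peak by
default). With pressure zeroed at its diastolic value, the forward and
backward pressure waves are

    Pf = (P + Q*Zc) / 2        Pb = (P - Q*Zc) / 2

so Pf + Pb reconstructs the diastole-zeroed pressure at every sample, and
reflection magnitude is the ratio of backward to forward amplitudes
(max - min of each series). Reflection load indices follow: QZc (systolic
time integral of Q*Zc, mmHg*ms), wasted pressure effort (the systolic excess
of measured pressure over QZc) and their ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .errors import DegenerateBeatError, FitError, ShapeError, WindowError
from .waveform_io import convert_zc_units

__all__ = [
    "WsaResult",
    "ZcFit",
    "estimate_zc",
    "separate_waves",
    "wasted_effort_indices",
    "reflection_magnitude",
    "report_zc_units",
]

_DEFAULT = AnalysisConfig()


@dataclass
class ZcFit:
    """Diagnostics of the early-systolic slope fit."""

    zc: float
    n_points: int
    r_squared: float
    window: tuple[int, int]


@dataclass
class WsaResult:
    """Forward/backward decomposition of one beat.

    ``pf``/``pb`` are diastole-zeroed pressure series in mmHg; amplitudes are
    max - min; ``rm = pb_amp / pf_amp``.
    """

    zc: float
    pf: np.ndarray
    pb: np.ndarray
    pf_amp: float
    pb_amp: float
    rm: float
    fit: ZcFit | None = None

    @property
    def zc_min_per_l(self) -> float:
        return convert_zc_units(self.zc)


def reflection_magnitude(pb_amp: float, pf_amp: float) -> float:
    """Reflection magnitude: backward over forward wave amplitude."""
    if pf_amp <= 0:
        raise DegenerateBeatError("forward wave amplitude must be positive")
    return pb_amp / pf_amp


def _fit_window(q: np.ndarray, fs_hz: float, config: AnalysisConfig) -> tuple[int, int]:
    qpk = int(np.argmax(q))
    qmax = q[qpk]
    if qmax <= 0:
        raise WindowError("flow never rises above zero")
    lo_thr = config.zc_window_low_frac * qmax
    hi_thr = config.zc_window_high_frac * qmax
    # Last sample before the peak at which flow is still at/below the onset
    # threshold: start of the rising limb.
    below = np.nonzero(q[:qpk + 1] <= lo_thr)[0]
    i_lo = int(below[-1]) if below.size else 0
    if config.zc_window_mode == "fixed_ms":
        i_hi = i_lo + int(round(config.zc_window_fixed_ms / 1000.0 * fs_hz))
        i_hi = min(i_hi, qpk)
    else:
        above = np.nonzero(q[i_lo:qpk + 1] >= hi_thr)[0]
        i_hi = i_lo + int(above[0]) if above.size else qpk
    return i_lo, i_hi


def estimate_zc(
    p: np.ndarray,
    q: np.ndarray,
    fs_hz: float,
    config: AnalysisConfig = _DEFAULT,
) -> ZcFit:
    """Estimate characteristic impedance from the early-systolic upstroke.

    Returns the slope (mmHg*s/mL) of diastole-zeroed pressure against flow
    over the rising limb, with fit diagnostics. Raises
    :class:`WindowError` with fewer than 4 samples in the window and
    :class:`FitError` for a non-positive slope (reflections contaminating the
    window or mis-segmentation).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.size != q.size:
        raise ShapeError("pressure and flow must have equal length")
    ps = p - p.min()
    i_lo, i_hi = _fit_window(q, fs_hz, config)
    if i_hi - i_lo + 1 < 4:
        raise WindowError(
            f"only {i_hi - i_lo + 1} samples in the impedance fit window"
        )
    x = q[i_lo:i_hi + 1]
    y = ps[i_lo:i_hi + 1]
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise FitError(f"non-positive pressure-flow slope ({slope:.4g})")
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return ZcFit(zc=float(slope), n_points=x.size, r_squared=r2,
                 window=(i_lo, i_hi))


def separate_waves(p: np.ndarray, q: np.ndarray, zc: float,
                   fit: ZcFit | None = None) -> WsaResult:
    """Decompose a pressure beat into forward and backward waves."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.size != q.size:
        raise ShapeError("pressure and flow must have equal length")
    if zc <= 0:
        raise FitError("zc must be positive")
    ps = p - p.min()
    qzc = q * zc
    pf = 0.5 * (ps + qzc)
    pb = 0.5 * (ps - qzc)
    pf_amp = float(pf.max() - pf.min())
    pb_amp = float(pb.max() - pb.min())
    # degenerate (flat) forward wave: no reflection magnitude is defined
    rm = reflection_magnitude(pb_amp, pf_amp) if pf_amp > 0 else float("nan")
    return WsaResult(zc=float(zc), pf=pf, pb=pb, pf_amp=pf_amp, pb_amp=pb_amp,
                     rm=rm, fit=fit)


def wasted_effort_indices(
    p: np.ndarray, q: np.ndarray, zc: float, dn_idx: int, fs_hz: float
) -> tuple[float, float, float]:
    """Systolic reflection-load integrals over [foot, dicrotic notch].

    Returns ``(qzc_int, wasted_effort, wasted_ratio)`` in mmHg*ms (ratio
    dimensionless). The wasted-effort integrand is clamped at zero where
    Q*Zc exceeds measured pressure.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.size != q.size:
        raise ShapeError("pressure and flow must have equal length")
    if not 0 < dn_idx < p.size:
        raise ShapeError(f"dn_idx {dn_idx} outside the beat")
    dt_ms = 1000.0 / fs_hz
    ps = (p - p.min())[:dn_idx + 1]
    qzc = (q * zc)[:dn_idx + 1]
    qzc_int = float(np.trapezoid(qzc, dx=dt_ms))
    if qzc_int <= 0:
        raise DegenerateBeatError("non-positive systolic flow integral")
    wasted = float(np.trapezoid(np.maximum(ps - qzc, 0.0), dx=dt_ms))
    return qzc_int, wasted, wasted / qzc_int


def report_zc_units(zc: float) -> float:
    """Convert Zc from mmHg*s/mL to the reporting unit mmHg*min/L."""
    if zc <= 0:
        raise FitError("zc must be positive")
    return convert_zc_units(zc)
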