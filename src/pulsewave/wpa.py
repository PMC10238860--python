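"""Wave power analysis.

Wave power is the per-sample product of pressure and flow increments,
``dPi = dP * dQ``, computed on a canonical 500 Hz grid so magnitudes are
comparable across recordings, and expressed in microwatts
(1 mmHg * 1 mL/s = 133.322 uW). Waves are classified by the signs of the
power, pressure and flow increments:

* forward compression wave (FCW): +dPi, +dP, +dQ, early systole;
* forward expansion wave (FEW):   +dPi, -dP, -dQ, late systole;
* backward compression wave (BCW): -dPi, +dP, -dQ, mid systole
  (its absence is a normal finding, not an error).

Net wave power with sign-based classification is used throughout (no
impedance-based forward/backward power separation). The FCW/FEW height
ratio is dimensionless and invariant under any rescaling of the flow units,
which is what licenses computing it from an uncalibrated synthetic flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .config import AnalysisConfig
from .errors import ClassificationError, ShapeError
from .waveform_io import MMHG_MLS_TO_UW

__all__ = [
    "WavePeak",
    "WpaResult",
    "wave_power",
    "classify_waves",
    "fcw_few_ratio",
]

_DEFAULT = AnalysisConfig()


@dataclass(frozen=True)
class WavePeak:
    """One classified wave: peak time (ms from foot) and height (uW).

    Heights are positive magnitudes; for the backward compression wave the
    magnitude of the negative power trough is reported.
    """

    time_ms: float
    height: float


@dataclass
class WpaResult:
    fcw: WavePeak
    few: WavePeak | None
    bcw: WavePeak | None

    @property
    def fcw_few_ratio(self) -> float | None:
        if self.few is None or self.few.height <= 0:
            return None
        return self.fcw.height / self.few.height


def _to_canonical(x: np.ndarray, fs_hz: float, target_hz: float) -> np.ndarray:
    if abs(fs_hz - target_hz) < 1e-9:
        return np.asarray(x, dtype=float)
    duration = (x.size - 1) / fs_hz
    n_new = max(int(round(duration * target_hz)) + 1, 3)
    t_old = np.arange(x.size) / fs_hz
    t_new = np.linspace(0.0, duration, n_new)
    return np.interp(t_new, t_old, x)


def wave_power(
    p: np.ndarray,
    q: np.ndarray,
    fs_hz: float,
    config: AnalysisConfig = _DEFAULT,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Per-sample wave power of one beat.

    Pressure and flow are resampled to the canonical grid
    (``wpa_resample_hz``), lightly smoothed, and differenced. Returns
    ``(dpi, dP, dQ, fs_grid)`` where ``dpi`` is in uW (uncalibrated flow
    yields uncalibrated power; only ratios are meaningful then).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.size != q.size:
        raise ShapeError("pressure and flow must have equal length")
    if p.size < 3:
        raise ShapeError("need at least 3 samples")
    fs_grid = config.wpa_resample_hz
    pc = _to_canonical(p, fs_hz, fs_grid)
    qc = _to_canonical(q, fs_hz, fs_grid)
    win = min(config.deriv_window, pc.size - 1)
    if win % 2 == 0:
        win -= 1
    if win >= 5:
        order = min(config.deriv_order, win - 1)
        pc = _signal.savgol_filter(pc, win, order)
        qc = _signal.savgol_filter(qc, win, order)
    dP = np.diff(pc)
    dQ = np.diff(qc)
    dpi = dP * dQ * MMHG_MLS_TO_UW
    return dpi, dP, dQ, fs_grid


def classify_waves(
    dpi: np.ndarray,
    dP: np.ndarray,
    dQ: np.ndarray,
    ppeak_idx: int,
    dn_idx: int,
    fs_hz: float,
    config: AnalysisConfig = _DEFAULT,
) -> WpaResult:
    """Identify FCW, FEW and BCW peaks from sign-classified wave power.

    ``ppeak_idx`` and ``dn_idx`` are the pressure-peak and dicrotic-notch
    sample indices on the same grid as ``dpi`` (the beat's foot is sample 0).
    The FCW is searched in early systole (foot to pressure peak), the FEW
    between the pressure peak and the notch plus a short margin, the BCW over
    systole up to the notch.
    """
    dpi = np.asarray(dpi, dtype=float)
    if not (dpi.size == dP.size == dQ.size):
        raise ShapeError("dpi, dP, dQ must have equal length")
    n = dpi.size
    dt_ms = 1000.0 / fs_hz
    ppeak = int(np.clip(ppeak_idx, 1, n))
    dn = int(np.clip(dn_idx, ppeak, n))
    margin = int(round(config.few_margin_ms / dt_ms))

    def best(lo: int, hi: int, mask_fn) -> WavePeak | None:
        lo = max(lo, 0)
        hi = min(hi, n)
        if hi <= lo:
            return None
        idx = np.arange(lo, hi)
        m = mask_fn(dpi[lo:hi], dP[lo:hi], dQ[lo:hi])
        if not np.any(m):
            return None
        cand = idx[m]
        k = cand[np.argmax(np.abs(dpi[cand]))]
        # Midpoint of the differenced interval, in ms from the foot.
        return WavePeak(time_ms=(k + 0.5) * dt_ms, height=float(abs(dpi[k])))

    fcw = best(0, ppeak, lambda s, a, b: (s > 0) & (a > 0) & (b > 0))
    if fcw is None:
        raise ClassificationError("no forward-compression-eligible sample")
    few = best(ppeak, dn + margin, lambda s, a, b: (s > 0) & (a < 0) & (b < 0))
    bcw = best(0, dn, lambda s, a, b: (s < 0) & (a > 0) & (b < 0))
    return WpaResult(fcw=fcw, few=few, bcw=bcw)


def fcw_few_ratio(fcw_height: float, few_height: float | None) -> float | None:
    """FCW/FEW height ratio; ``None`` when the FEW is absent or zero.

    Dimensionless and invariant under any common rescaling of the flow
    units.
    """
    if few_height is None or few_height <= 0:
        return None
    return fcw_height / few_height
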