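"""Pressure preprocessing: filtering, beat segmentation, ensemble averaging.

The chain mirrors standard arterial-waveform practice: polynomial
(Savitzky--Golay) smoothing plus a zero-phase low-pass, systolic peak / foot
detection with an amplitude-plausibility filter, grouping of eight
consecutive beats into a time- and amplitude-normalized ensemble mean, and a
finite-difference derivative chain (first through fifth order) on that mean
for landmark logic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import AnalysisConfig
from .errors import DetectionError, GroupingError, LengthError

__all__ = [
    "BeatSegment",
    "EnsembleBeat",
    "filter_pressure",
    "detect_beats",
    "ensemble_average",
    "derivative_chain",
]

_DEFAULT = AnalysisConfig()


@dataclass(frozen=True)
class BeatSegment:
    """Index span of one beat: diastolic foot, systolic peak, next foot."""

    onset_idx: int
    sys_peak_idx: int
    end_idx: int

    def __post_init__(self) -> None:
        if not self.onset_idx < self.sys_peak_idx < self.end_idx:
            raise DetectionError(
                f"beat indices out of order: {self.onset_idx} < "
                f"{self.sys_peak_idx} < {self.end_idx} violated"
            )

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.onset_idx + 1


@dataclass
class EnsembleBeat:
    """Mean normalized waveform of one group of consecutive beats.

    ``fn`` is the amplitude-normalized (min 0, max 1) mean of the members
    after each was resampled to a common length; ``d1``..``d5`` are its
    successive smoothed finite-difference derivatives. ``p_mean`` (and
    ``q_mean`` when flow is available) hold the *dimensional* signal-averaged
    beat for the pressure--flow analyses: members aligned at the foot on the
    original time grid and averaged over the shortest member, which keeps
    fixed-latency features (upstroke, incisura) coherent under period
    jitter. ``duration_s`` is the mean member duration so the normalized
    grid maps back to time via :meth:`wave_index`.
    """

    fn: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    d3: np.ndarray
    d4: np.ndarray
    d5: np.ndarray
    member_beats: list[BeatSegment]
    amp_scale: list[tuple[float, float]]
    duration_s: float
    fs_hz: float
    p_mean: np.ndarray | None = None
    q_mean: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.fn.size

    @property
    def fs_eff_hz(self) -> float:
        """Effective sampling rate of the normalized grid."""
        return (self.n - 1) / self.duration_s

    def member_index(self, member: int, k: float) -> int:
        """Map a normalized-grid index back to a sample offset within member
        ``member`` (relative to its onset), inverting the resampling."""
        seg = self.member_beats[member]
        return int(round(k * (seg.n_samples - 1) / (self.n - 1)))

    def wave_index(self, k: float) -> int:
        """Map a normalized-grid index onto the signal-averaged beat grid."""
        mean_len = self.duration_s * self.fs_hz
        idx = int(round(k * mean_len / (self.n - 1)))
        limit = self.p_mean.size - 1 if self.p_mean is not None else idx
        return min(max(idx, 0), limit)


def filter_pressure(
    p: np.ndarray, fs_hz: float, config: AnalysisConfig = _DEFAULT
) -> np.ndarray:
    """Savitzky--Golay smoothing followed by a zero-phase low-pass.

    Window 23 samples / order 2 and a 10 Hz cutoff by default. Zero-phase
    (forward-backward Butterworth) filtering leaves the peak of a symmetric
    pulse unmoved.
    """
    p = np.asarray(p, dtype=float)
    if p.size <= config.savgol_window:
        raise LengthError(
            f"series length {p.size} <= smoothing window {config.savgol_window}"
        )
    if fs_hz <= 2 * config.lowpass_hz:
        raise LengthError(
            f"fs {fs_hz} Hz leaves the {config.lowpass_hz} Hz cutoff above Nyquist"
        )
    smoothed = signal.savgol_filter(p, config.savgol_window, config.savgol_order)
    sos = signal.butter(config.lowpass_order, config.lowpass_hz, btype="low",
                        fs=fs_hz, output="sos")
    return signal.sosfiltfilt(sos, smoothed)


def smooth_signal(x: np.ndarray, config: AnalysisConfig = _DEFAULT) -> np.ndarray:
    """Savitzky--Golay measurement smoothing only (no low-pass).

    Used for the pressure--flow wave analyses, which need the dicrotic notch
    and early shoulder that the landmark-detection low-pass removes.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= config.savgol_window:
        raise LengthError(
            f"series length {x.size} <= smoothing window {config.savgol_window}"
        )
    return signal.savgol_filter(x, config.savgol_window, config.savgol_order)


def detect_beats(
    p: np.ndarray, fs_hz: float, config: AnalysisConfig = _DEFAULT
) -> list[BeatSegment]:
    """Segment a (filtered) pressure trace into beats.

    Systolic peaks are local maxima with prominence above a quarter of the
    5th--95th percentile pressure range, separated by a refractory interval
    (a fraction of the median beat period). Peaks whose amplitude deviates
    from the moving average of the last ``ma_peaks`` accepted peaks by more
    than ``plausibility_pct`` percent are rejected as artifacts. The foot of
    each beat is the diastolic nadir preceding its upstroke.
    """
    p = np.asarray(p, dtype=float)
    if p.size < 4:
        raise DetectionError("series too short for beat detection")
    span = np.percentile(p, 95) - np.percentile(p, 5)
    if span <= 1e-9:
        raise DetectionError("no pressure excursions: constant input")
    prominence = 0.25 * span

    peaks, _ = signal.find_peaks(p, prominence=prominence)
    if peaks.size < 2:
        raise DetectionError("fewer than two systolic peaks found")
    median_period = float(np.median(np.diff(peaks)))
    distance = max(1, int(round(config.refractory_frac * median_period)))
    peaks, _ = signal.find_peaks(p, prominence=prominence, distance=distance)

    # Amplitude plausibility: moving average over recent accepted peaks.
    accepted: list[int] = []
    recent: list[float] = []
    tol = config.plausibility_pct / 100.0
    for pk in peaks:
        height = p[pk]
        if recent:
            ma = float(np.mean(recent[-config.ma_peaks:]))
            scale = max(abs(ma), 1e-12)
            if abs(height - ma) > tol * scale:
                continue  # implausible peak: rejected, not imputed
        accepted.append(int(pk))
        recent.append(float(height))
    if len(accepted) < 2:
        raise DetectionError("fewer than two plausible beats detected")

    # Feet: nadir between consecutive peaks (and before the first peak).
    feet: list[int] = []
    lookback = int(round(median_period))
    start = max(0, accepted[0] - lookback)
    feet.append(start + int(np.argmin(p[start:accepted[0] + 1])))
    for left, right in zip(accepted[:-1], accepted[1:]):
        feet.append(left + int(np.argmin(p[left:right + 1])))
    tail_start = accepted[-1]
    tail_foot = tail_start + int(np.argmin(p[tail_start:]))

    segments: list[BeatSegment] = []
    bounds = feet + [tail_foot]
    for i, peak in enumerate(accepted):
        onset, end = bounds[i], bounds[i + 1]
        if onset < peak < end:
            segments.append(BeatSegment(onset, peak, end))
    if len(segments) < 1:
        raise DetectionError("no complete beats segmented")
    return segments


def _resample(x: np.ndarray, n: int) -> np.ndarray:
    src = np.linspace(0.0, 1.0, x.size)
    dst = np.linspace(0.0, 1.0, n)
    return np.interp(dst, src, x)


def ensemble_average(
    beats: list[BeatSegment],
    p: np.ndarray,
    config: AnalysisConfig = _DEFAULT,
    q: np.ndarray | None = None,
    fs_hz: float = 500.0,
    p_dim: np.ndarray | None = None,
) -> list[EnsembleBeat]:
    """Average consecutive groups of beats into normalized ensemble waveforms.

    Each complete group of ``group_size`` consecutive beats yields one
    :class:`EnsembleBeat`: members are resampled to a common length
    (``ensemble_n``), min--max amplitude-normalized, and averaged; the
    incomplete trailing group is discarded. Dimensional signal-averaged
    beats (foot-aligned on the original grid, truncated to the shortest
    member) of pressure and flow are retained for the wave analyses;
    ``p_dim`` supplies a separately smoothed pressure for those (the
    normalized waveform always comes from ``p``).
    """
    p = np.asarray(p, dtype=float)
    p_for_mean = p if p_dim is None else np.asarray(p_dim, dtype=float)
    g = config.group_size
    if len(beats) < g:
        raise GroupingError(f"{len(beats)} beats < group size {g}")
    n = config.ensemble_n
    ensembles: list[EnsembleBeat] = []
    for gi in range(len(beats) // g):
        members = beats[gi * g:(gi + 1) * g]
        wave_len = min(seg.n_samples for seg in members)
        norm_stack, dim_stack, q_stack, amps = [], [], [], []
        for seg in members:
            res = _resample(p[seg.onset_idx:seg.end_idx + 1], n)
            lo, hi = float(res.min()), float(res.max())
            norm_stack.append((res - lo) / (hi - lo))
            dim_stack.append(p_for_mean[seg.onset_idx:seg.onset_idx + wave_len])
            amps.append((lo, hi))
            if q is not None:
                q_stack.append(q[seg.onset_idx:seg.onset_idx + wave_len])
        fn = np.mean(norm_stack, axis=0)
        # Renormalize the mean: averaging individually normalized members
        # can leave min/max marginally off 0/1.
        fn = (fn - fn.min()) / (fn.max() - fn.min())
        d1, d2, d3, d4, d5 = derivative_chain(fn, config)
        ensembles.append(EnsembleBeat(
            fn=fn, d1=d1, d2=d2, d3=d3, d4=d4, d5=d5,
            member_beats=list(members),
            amp_scale=amps,
            duration_s=float(np.mean([s.n_samples - 1 for s in members])) / fs_hz,
            fs_hz=fs_hz,
            p_mean=np.mean(dim_stack, axis=0),
            q_mean=np.mean(q_stack, axis=0) if q_stack else None,
        ))
    return ensembles


def derivative_chain(
    fn: np.ndarray, config: AnalysisConfig = _DEFAULT
) -> tuple[np.ndarray, ...]:
    """First through fifth finite-difference derivatives of ``fn``.

    Successive central differences (one-sided at the endpoints) with light
    Savitzky--Golay re-smoothing between orders; repeated differencing of a
    ~500-sample waveform is numerically unusable at fifth order without it.
    Derivatives are on the normalized grid (unit sample spacing): only their
    signs and zero crossings are consumed downstream.
    """
    fn = np.asarray(fn, dtype=float)
    if fn.size < max(11, config.deriv_window):
        raise LengthError(f"waveform length {fn.size} too short for derivatives")
    out = []
    d = fn
    for _ in range(5):
        d = np.gradient(d)
        d = signal.savgol_filter(d, config.deriv_window, config.deriv_order)
        out.append(d)
    return tuple(out)
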