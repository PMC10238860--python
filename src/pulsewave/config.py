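"""Analysis configuration.

A single flat dataclass holds every tunable of the processing chain, with the
defaults used throughout the package. A key--value text file (plain
``key: value`` lines, i.e. trivially YAML-compatible) can override any field.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the full analysis chain.

    Attributes
    ----------
    savgol_window, savgol_order:
        Savitzky--Golay pre-smoothing of the raw pressure (samples / order).
    lowpass_hz, lowpass_order:
        Zero-phase (forward-backward Butterworth) low-pass cutoff and order
        applied after the polynomial smoother. Low orders preserve the
        dicrotic notch and early shoulder better; the cutoff is fixed by the
        acquisition protocol.
    ensemble_n:
        Common length every beat is resampled to before ensemble averaging.
    group_size:
        Number of consecutive beats averaged into one ensemble waveform.
    refractory_frac:
        Minimum peak separation as a fraction of the median beat period.
    plausibility_pct:
        Maximum deviation (percent) of a systolic peak from the moving
        average of recent peak amplitudes before it is rejected as artifact.
    ma_peaks:
        Number of recent peaks in that moving average.
    deriv_window, deriv_order:
        Savitzky--Golay re-smoothing applied between successive finite
        differences of the normalized ensemble waveform.
    zc_window_low_frac, zc_window_high_frac:
        Early-systolic impedance fit window as fractions of peak flow.
    zc_window_mode:
        ``"fraction"`` (default) or ``"fixed_ms"`` for a fixed-duration
        window starting at flow onset.
    zc_window_fixed_ms:
        Window duration in the fixed-duration mode.
    wpa_resample_hz:
        Canonical grid for per-sample pressure/flow differences, so wave
        power is comparable across recordings of different sampling rates.
    few_margin_ms:
        How far past the dicrotic notch the forward-expansion-wave search
        window extends.
    """

    savgol_window: int = 23
    savgol_order: int = 2
    lowpass_hz: float = 10.0
    lowpass_order: int = 2
    ensemble_n: int = 500
    group_size: int = 8
    refractory_frac: float = 0.25
    plausibility_pct: float = 30.0
    ma_peaks: int = 10
    deriv_window: int = 11
    deriv_order: int = 3
    zc_window_low_frac: float = 0.05
    zc_window_high_frac: float = 0.50
    zc_window_mode: str = "fraction"
    zc_window_fixed_ms: float = 60.0
    wpa_resample_hz: float = 500.0
    few_margin_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.savgol_window % 2 == 0 or self.savgol_window < 3:
            raise ParameterError("savgol_window must be odd and >= 3")
        if self.savgol_order >= self.savgol_window:
            raise ParameterError("savgol_order must be < savgol_window")
        if self.lowpass_hz <= 0:
            raise ParameterError("lowpass_hz must be positive")
        if self.lowpass_order < 1:
            raise ParameterError("lowpass_order must be >= 1")
        if self.group_size < 1:
            raise ParameterError("group_size must be >= 1")
        if self.zc_window_mode not in ("fraction", "fixed_ms"):
            raise ParameterError("zc_window_mode must be 'fraction' or 'fixed_ms'")
        if not 0.0 <= self.zc_window_low_frac < self.zc_window_high_frac <= 1.0:
            raise ParameterError(
                "zc window fractions must satisfy 0 <= low < high <= 1"
            )

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load overrides from a key--value (YAML mapping) file."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ParameterError(f"config file {path} is not a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        """Short stable hash of the configuration, for report provenance."""
        payload = repr(sorted(dataclasses.asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
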