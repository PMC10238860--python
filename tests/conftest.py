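import numpy as np
import pytest

from pulsewave.config import AnalysisConfig
from pulsewave.synthetic_data import hf_preset, simulate_beat, simulate_recording
from pulsewave import preprocess, pwa


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def clean_baseline_beat():
    """One noise-free baseline beat with exact ground truth."""
    params = hf_preset("baseline", noise_sd_mmhg=0.0, noise_sd_flow=0.0)
    return simulate_beat(params)


@pytest.fixture(scope="session")
def analyzed_ensemble(config):
    """Noise-free 8-beat baseline recording taken through preprocessing.

    Returns (recording, ensemble, landmarks, params); the ensemble carries
    dimensional pressure/flow means on the lightly smoothed track.
    """
    params = hf_preset("baseline", noise_sd_mmhg=0.0, noise_sd_flow=0.0, seed=3)
    rec = simulate_recording(params, 8)
    p_f = preprocess.filter_pressure(rec.p, rec.fs_hz, config)
    p_w = preprocess.smooth_signal(rec.p, config)
    q_w = preprocess.smooth_signal(rec.q, config)
    beats = preprocess.detect_beats(p_f, rec.fs_hz, config)
    ens = preprocess.ensemble_average(beats, p_f, config, q=q_w,
                                      fs_hz=rec.fs_hz, p_dim=p_w)[0]
    lm = pwa.locate_landmarks(ens)
    assert lm.valid, lm.reason
    return rec, ens, lm, params


def wave_landmarks(ens, lm):
    """Landmarks mapped from the normalized grid onto the signal-averaged
    beat grid, as the pipeline does before the wave analyses."""
    return pwa.PwaLandmarks(
        p1_idx=ens.wave_index(lm.p1_idx),
        p2_idx=ens.wave_index(lm.p2_idx),
        dn_idx=ens.wave_index(lm.dn_idx),
        augmentation_sign=lm.augmentation_sign, valid=True)


def make_ensemble(fn, d1, d2, d3, d4, d5):
    """EnsembleBeat wrapper around externally supplied derivative arrays."""
    n = len(fn)
    seg = preprocess.BeatSegment(0, max(int(np.argmax(fn)), 1), n - 1)
    return preprocess.EnsembleBeat(
        fn=np.asarray(fn, float), d1=np.asarray(d1, float),
        d2=np.asarray(d2, float), d3=np.asarray(d3, float),
        d4=np.asarray(d4, float), d5=np.asarray(d5, float),
        member_beats=[seg], amp_scale=[(0.0, 1.0)],
        duration_s=1.0, fs_hz=float(n - 1))
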