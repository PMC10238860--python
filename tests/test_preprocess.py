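"""Filtering, beat detection, ensemble averaging, derivative chain."""

import numpy as np
import pytest

from pulsewave import preprocess
from pulsewave.config import AnalysisConfig
from pulsewave.errors import DetectionError, GroupingError, LengthError
from pulsewave.synthetic_data import hf_preset, simulate_recording

FS = 500.0


class TestFilterPressure:
    def test_constant_series_is_preserved(self, config):
        x = np.full(1000, 80.0)
        np.testing.assert_allclose(
            preprocess.filter_pressure(x, FS, config), x, atol=1e-9)

    def test_passband_and_stopband(self, config):
        t = np.arange(0, 4, 1 / FS)
        inner = slice(500, -500)
        low = preprocess.filter_pressure(np.sin(2 * np.pi * 2.0 * t), FS, config)
        assert low[inner].max() > 0.95
        high = preprocess.filter_pressure(np.sin(2 * np.pi * 50.0 * t), FS, config)
        assert high[inner].max() < 0.10

    def test_zero_phase_keeps_symmetric_peak_in_place(self, config):
        t = np.arange(0, 2, 1 / FS)
        x = np.exp(-((t - 1.0) ** 2) / (2 * 0.05**2))
        y = preprocess.filter_pressure(x, FS, config)
        assert abs(int(np.argmax(y)) - int(np.argmax(x))) <= 1

    def test_short_series_raises_length_error(self, config):
        with pytest.raises(LengthError):
            preprocess.filter_pressure(np.zeros(10), FS, config)


class TestDetectBeats:
    def test_artifact_spike_does_not_change_beat_count(self, config):
        rec = simulate_recording(hf_preset("baseline", seed=4), 10)
        base = preprocess.detect_beats(
            preprocess.filter_pressure(rec.p, FS, config), FS, config)
        spiked = rec.p.copy()
        k = rec.meta["onsets"][4] + 30
        spiked[k:k + 5] = rec.p.max() + 30.0
        with_spike = preprocess.detect_beats(
            preprocess.filter_pressure(spiked, FS, config), FS, config)
        assert len(with_spike) == len(base)

    def test_constant_pressure_is_detection_error(self, config):
        with pytest.raises(DetectionError):
            preprocess.detect_beats(np.full(5000, 90.0), FS, config)

    def test_segments_ordered_and_non_overlapping(self, config):
        rec = simulate_recording(hf_preset("baseline", seed=8), 12)
        beats = preprocess.detect_beats(
            preprocess.filter_pressure(rec.p, FS, config), FS, config)
        for a, b in zip(beats[:-1], beats[1:]):
            assert a.onset_idx < a.sys_peak_idx < a.end_idx
            assert a.end_idx <= b.onset_idx

    def test_translation_shifts_all_indices(self, config):
        rec = simulate_recording(
            hf_preset("baseline", noise_sd_mmhg=0.0, noise_sd_flow=0.0, seed=2),
            12)
        k = 57
        full = preprocess.detect_beats(rec.p, FS, config)
        cut = preprocess.detect_beats(rec.p[k:], FS, config)
        # compare interior beats present in both segmentations
        full_on = {s.onset_idx for s in full}
        shifted = {s.onset_idx + k for s in cut}
        common = sorted(full_on & shifted)
        assert len(common) >= 9


class TestEnsembleAverage:
    def test_identical_beats_reproduce_the_normalized_member(self, config):
        from pulsewave.synthetic_data import simulate_beat

        beat = simulate_beat(hf_preset("baseline", noise_sd_mmhg=0.0,
                                       noise_sd_flow=0.0))
        n = beat.p.size
        p = np.tile(beat.p, 8)
        beats = [preprocess.BeatSegment(k * n, k * n + int(np.argmax(beat.p)),
                                        (k + 1) * n - 1) for k in range(8)]
        ens = preprocess.ensemble_average(beats, p, config, fs_hz=FS)[0]
        seg = beat.p[:n]
        member = np.interp(np.linspace(0, 1, config.ensemble_n),
                           np.linspace(0, 1, seg.size), seg)
        member = (member - member.min()) / (member.max() - member.min())
        np.testing.assert_allclose(ens.fn, member, atol=1e-9)

    @pytest.mark.parametrize("n_beats,n_groups", [(16, 2), (15, 1), (8, 1)])
    def test_grouping_arithmetic(self, config, n_beats, n_groups, ):
        rec = simulate_recording(hf_preset("baseline", seed=6), n_beats)
        beats = preprocess.detect_beats(
            preprocess.filter_pressure(rec.p, FS, config), FS, config)
        assert len(beats) == n_beats
        groups = preprocess.ensemble_average(beats, rec.p, config, fs_hz=FS)
        assert len(groups) == n_groups

    def test_too_few_beats_is_grouping_error(self, config):
        rec = simulate_recording(hf_preset("baseline", seed=6), 4)
        beats = preprocess.detect_beats(
            preprocess.filter_pressure(rec.p, FS, config), FS, config)
        with pytest.raises(GroupingError):
            preprocess.ensemble_average(beats, rec.p, config, fs_hz=FS)

    def test_normalization_bounds(self, analyzed_ensemble):
        _, ens, _, _ = analyzed_ensemble
        assert ens.fn.min() == pytest.approx(0.0, abs=1e-9)
        assert ens.fn.max() == pytest.approx(1.0, abs=1e-9)
        assert len(ens.member_beats) == 8

    def test_member_index_inverts_resampling(self, analyzed_ensemble):
        _, ens, _, _ = analyzed_ensemble
        n = ens.n
        for j, seg in enumerate(ens.member_beats):
            len_j = seg.n_samples
            for k in (0, n // 3, n - 1):
                expect = int(round(k * (len_j - 1) / (n - 1)))
                assert ens.member_index(j, k) == expect


class TestDerivativeChain:
    def test_linear_ramp(self, config):
        fn = np.linspace(0.0, 1.0, 400)
        d1, d2, d3, d4, d5 = preprocess.derivative_chain(fn, config)
        inner = slice(20, -20)
        slope = 1.0 / 399
        np.testing.assert_allclose(d1[inner], slope, rtol=1e-9)
        for d in (d2, d3, d4, d5):
            assert np.abs(d[inner]).max() < 1e-6 * slope

    def test_sine_second_derivative_matches_closed_form(self, config):
        n = 500
        t = np.linspace(0.0, 1.0, n)
        fn = np.sin(2 * np.pi * t)
        _, d2, *_ = preprocess.derivative_chain(fn, config)
        h = 1.0 / (n - 1)
        expect = -((2 * np.pi) ** 2) * fn * h**2
        inner = slice(25, -25)
        np.testing.assert_allclose(d2[inner], expect[inner],
                                   atol=0.01 * np.abs(expect).max())

    def test_cubic_has_vanishing_fourth_and_fifth(self, config):
        t = np.linspace(0.0, 1.0, 500)
        fn = 2.0 * t**3 - 1.5 * t**2 + 0.25 * t
        _, _, d3, d4, d5 = preprocess.derivative_chain(fn, config)
        inner = slice(60, -60)  # one-sided endpoint stencils excluded
        scale = np.abs(d3[inner]).max()
        assert np.abs(d4[inner]).max() < 1e-4 * scale
        assert np.abs(d5[inner]).max() < 1e-4 * scale

    def test_too_short_input_raises(self, config):
        with pytest.raises(LengthError):
            preprocess.derivative_chain(np.zeros(5), config)
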