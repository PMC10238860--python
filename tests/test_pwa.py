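"""Landmark logic and pulse-wave indices."""

import numpy as np
import pytest
from scipy.interpolate import UnivariateSpline

from conftest import make_ensemble
from pulsewave import pwa
from pulsewave.errors import AggregationError
from pulsewave.pwa import (
    PwaIndices,
    aggregate_session,
    compute_pwa_indices,
    locate_landmarks,
    zero_crossings,
)


def _hump(n=500, peak=250):
    x = np.arange(n)
    return np.exp(-((x - peak) ** 2) / (2 * 60.0**2))


def _crafted(d5_at_peak: float):
    """Derivative arrays with exactly known crossing structure.

    d1 peaks at 100; d4 = sin(2*pi*(k-100)/80) has +/- crossings at
    140, 220, 300, ... and -/+ crossings at 180, 260, ...; d3 first
    +/- crossing after the peak (250) is at 280.
    """
    n = 500
    k = np.arange(n)
    fn = _hump(n, 250)
    d1 = np.exp(-((k - 100) ** 2) / (2 * 30.0**2))
    d4 = np.sin(2 * np.pi * (k - 100) / 80.0)
    d3 = np.cos(2 * np.pi * (k - 250) / 120.0)
    d2 = np.zeros(n)
    d5 = np.full(n, d5_at_peak)
    return make_ensemble(fn, d1, d2, d3, d4, d5)


class TestBranchRule:
    def test_negative_d5_selects_positive_augmentation(self):
        lm = locate_landmarks(_crafted(-1.0))
        assert lm.valid
        assert lm.augmentation_sign == "positive"
        assert lm.p2_idx == 250          # the pressure maximum
        assert lm.p1_idx == 220          # second +/- d4 crossing after max d1
        assert lm.dn_idx == 280          # first +/- d3 crossing after the peak
        assert lm.p1_idx < lm.p2_idx < lm.dn_idx

    def test_positive_d5_selects_negative_augmentation(self):
        lm = locate_landmarks(_crafted(+1.0))
        assert lm.valid
        assert lm.augmentation_sign == "negative"
        assert lm.p1_idx == 250          # P1 at the pressure maximum
        assert lm.p2_idx == 260          # first -/+ d4 crossing after P1
        assert lm.dn_idx == 280

    def test_exact_zero_d5_tie_breaks_to_negative(self):
        lm = locate_landmarks(_crafted(0.0))
        assert lm.valid
        assert lm.augmentation_sign == "negative"
        assert lm.p1_idx == 250

    def test_missing_crossings_flag_beat_invalid_with_reason(self):
        n = 500
        flat = np.zeros(n)
        ens = make_ensemble(_hump(n), flat, flat, flat, flat,
                            np.full(n, -1.0))
        lm = locate_landmarks(ens)
        assert not lm.valid
        assert "crossing" in lm.reason


class TestLandmarksOnSmoothWaveform:
    """Chain-estimated landmarks agree with an independent spline oracle."""

    def test_two_bump_waveform_matches_spline_oracle(self, config):
        from pulsewave.preprocess import derivative_chain

        x = np.linspace(0.0, 1.0, 500)
        fn = (np.exp(-((x - 0.25) ** 2) / (2 * 0.06**2))
              + 0.5 * np.exp(-((x - 0.50) ** 2) / (2 * 0.09**2)))
        fn = (fn - fn.min()) / (fn.max() - fn.min())
        d1, d2, d3, d4, d5 = derivative_chain(fn, config)
        ens = make_ensemble(fn, d1, d2, d3, d4, d5)
        lm = locate_landmarks(ens)
        assert lm.valid

        sp = UnivariateSpline(np.arange(500), fn, k=5, s=1e-10)
        grid = np.arange(500)
        peak = int(np.argmax(fn))
        if lm.augmentation_sign == "negative":
            assert lm.p1_idx == peak
            oracle = zero_crossings(sp.derivative(4)(grid), "up", start=peak)[0]
            assert abs(lm.p2_idx - oracle) <= 3
        else:
            m1 = int(np.argmax(d1))
            oracle = zero_crossings(sp.derivative(4)(grid), "down", start=m1)[1]
            assert abs(lm.p1_idx - oracle) <= 3
        dn_oracle = zero_crossings(sp.derivative(3)(grid), "down", start=peak)[0]
        assert abs(lm.dn_idx - dn_oracle) <= 3


class TestLandmarksOnSimulatedBeats:
    def test_notch_lands_near_true_end_ejection(self, analyzed_ensemble):
        _, ens, lm, params = analyzed_ensemble
        dn_ms = lm.dn_idx / (ens.n - 1) * ens.duration_s * 1000.0
        assert abs(dn_ms - params.ed_ms) <= 30.0

    def test_landmarks_are_ordered_within_beat(self, analyzed_ensemble):
        _, ens, lm, _ = analyzed_ensemble
        assert 0 <= lm.p1_idx < lm.dn_idx < ens.n - 1


def triangle_beat():
    """Closed-form toy: foot 80 mmHg, linear to 120 at 100 ms, linear to
    95 mmHg at 300 ms (the notch), then flat diastole to 400 ms; 1 kHz."""
    fs = 1000.0
    up = np.linspace(80.0, 120.0, 101)
    down = np.linspace(120.0, 95.0, 201)[1:]
    tail = np.full(100, 95.0)
    return np.concatenate([up, down, tail]), fs


class TestPwaIndices:
    def test_triangle_closed_form_areas(self):
        p, fs = triangle_beat()
        idx = compute_pwa_indices(p, p1_idx=100, p2_idx=200, dn_idx=300,
                                  fs_hz=fs, augmentation_sign="negative")
        assert idx.ew == pytest.approx(0.0, abs=1e-9)
        assert idx.psa == pytest.approx(7500.0, rel=1e-9)
        assert idx.delta_spti == pytest.approx(24000.0, rel=1e-9)
        assert idx.ed_ms == pytest.approx(300.0)

    def test_time_decomposition_identity(self):
        p, fs = triangle_beat()
        idx = compute_pwa_indices(p, 100, 200, 300, fs, "negative")
        assert idx.ed_ms == pytest.approx(idx.tr_ms + idx.sdr_ms, rel=1e-9)

    def test_area_decomposition_identity_on_simulated_beats(
            self, analyzed_ensemble, config):
        rec, ens, lm, _ = analyzed_ensemble
        from pulsewave.preprocess import filter_pressure
        p_f = filter_pressure(rec.p, rec.fs_hz, config)
        per_beat = pwa.indices_for_ensemble(ens, lm, p_f, rec.fs_hz)
        assert len(per_beat) == 8
        for b in per_beat:
            assert b.ed_ms == pytest.approx(b.tr_ms + b.sdr_ms, rel=1e-6)
            assert b.spti == pytest.approx(b.delta_spti + b.psa + b.ew,
                                           rel=1e-6)
            assert min(b.ew, b.psa, b.spti, b.dpti) >= 0.0

    def test_pressure_scaling_scales_areas_linearly(self):
        p, fs = triangle_beat()
        a = compute_pwa_indices(p, 100, 200, 300, fs, "negative")
        b = compute_pwa_indices(3.0 * p, 100, 200, 300, fs, "negative")
        assert b.psa == pytest.approx(3.0 * a.psa, rel=1e-9)
        assert b.spti == pytest.approx(3.0 * a.spti, rel=1e-9)
        assert b.ap == pytest.approx(3.0 * a.ap, rel=1e-9)
        # timings are unchanged by amplitude scaling
        assert b.tr_ms == a.tr_ms and b.ed_ms == a.ed_ms


class TestAggregateSession:
    def _indices(self, psa):
        return PwaIndices(sbp=120, dbp=80, map=95, hr=90, ap=5, ed_ms=300,
                          tr_ms=100, sdr_ms=200, ew=0.0, psa=psa, spti=31500,
                          delta_spti=24000, dpti=9500)

    def test_identical_beats_have_zero_sd(self):
        agg = aggregate_session([self._indices(7000.0)] * 4)
        assert agg["psa_mean"] == pytest.approx(7000.0)
        assert agg["psa_sd"] == 0.0
        assert agg["n_beats"] == 4

    def test_mean_of_two_beats(self):
        agg = aggregate_session([self._indices(7000.0), self._indices(8000.0)],
                                n_excluded=1)
        assert agg["psa_mean"] == pytest.approx(7500.0)
        assert agg["n_excluded"] == 1

    def test_no_valid_beats_is_aggregation_error(self):
        with pytest.raises(AggregationError):
            aggregate_session([])
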