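import numpy as np
import pytest
from hypothesis import given, strategies as st
import hypothesis.extra.numpy as hnp

from bedposture import (
    BedGeometry, FilterSpec, LoadCellRecording, RespSeries, FEATURE_NAMES,
    compute_com, detect_breath_extrema, extract_features, isolate_cardiac,
    isolate_respiration, resp_angle,
)
from bedposture.features import read_feature_table, write_feature_table
from bedposture.signal_model import ValidationError

FS = 50.0


def recording_from(lh, rh, lf, rf, w=1.0, length=2.0):
    return LoadCellRecording(sample_rate=FS, lh=lh, rh=rh, lf=lf, rf=rf,
                             geometry=BedGeometry(w, length))


# ---------------------------------------------------------------------------
# Centre of mass
# ---------------------------------------------------------------------------

class TestComputeCom:
    @pytest.mark.parametrize("forces, w, length, expected", [
        ((100, 100, 100, 100), 1.0, 2.0, (0.0, 0.0)),   # symmetric load
        ((10, 0, 0, 0), 1.0, 2.0, (0.5, 1.0)),           # all weight on LH corner
        ((30, 30, 10, 10), 1.0, 2.0, (0.0, 0.5)),        # head-heavy, centred laterally
    ])
    def test_direct_substitution(self, forces, w, length, expected):
        lh, rh, lf, rf = (np.full(3, f, dtype=float) for f in forces)
        com = compute_com(recording_from(lh, rh, lf, rf, w, length))
        np.testing.assert_allclose(com.com_x, expected[0], atol=1e-15)
        np.testing.assert_allclose(com.com_y, expected[1], atol=1e-15)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(42)
        n = 10_000
        forces = rng.uniform(1.0, 500.0, size=(4, n))
        w, l = 0.95, 1.93
        rec = recording_from(*forces, w=w, length=l)
        com = compute_com(rec)
        for i in range(0, n, 997):  # spot-check a spread of samples
            lh, rh, lf, rf = forces[:, i]
            total = lh + rh + lf + rf
            ex = (w / 2) * (lh + lf - rh - rf) / total
            ey = (l / 2) * (lh + rh - lf - rf) / total
            assert abs(com.com_x[i] - ex) <= 1e-12 * max(1, abs(ex))
            assert abs(com.com_y[i] - ey) <= 1e-12 * max(1, abs(ey))

    def test_empty_bed_names_sample(self):
        lh = np.array([100.0, 0.2, 100.0])
        z = np.array([100.0, 0.2, 100.0])
        with pytest.raises(ValidationError, match="sample 1"):
            compute_com(recording_from(lh, z, z, z))

    @given(hnp.arrays(float, (4, 16), elements=st.floats(0.0, 1000.0)))
    def test_com_bounded_by_footprint(self, forces):
        if forces.sum(axis=0).min() <= 1.0:
            forces = forces + 1.0
        com = compute_com(recording_from(*forces, w=1.0, length=2.0))
        assert np.all(np.abs(com.com_x) <= 0.5 + 1e-12)
        assert np.all(np.abs(com.com_y) <= 1.0 + 1e-12)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def com_sinusoid(freq, duration=120.0, amp=1.0):
    from bedposture.features import CoMSeries
    t = np.arange(int(duration * FS)) / FS
    x = amp * np.sin(2 * np.pi * freq * t)
    return CoMSeries(sample_rate=FS, com_x=x, com_y=x.copy()), t


class TestRespiratoryFilter:
    def test_zero_in_zero_out(self):
        from bedposture.features import CoMSeries
        com = CoMSeries(FS, np.zeros(6000), np.zeros(6000))
        resp = isolate_respiration(com)
        np.testing.assert_allclose(resp.com_resp_x, 0.0, atol=1e-12)

    def test_in_band_sinusoid_preserved_zero_phase(self):
        com, t = com_sinusoid(0.25)
        resp = isolate_respiration(com, detect_extrema=False)
        mid = slice(1000, -1000)  # away from edge transients
        assert np.max(np.abs(resp.com_resp_x[mid])) >= 0.95
        # peaks of sin(2*pi*0.25 t) sit at t = 1 + 4k
        resp.t_max, resp.t_min = detect_breath_extrema(resp)
        peaks = resp.t_max[(resp.t_max > 20) & (resp.t_max < 100)]
        analytic = 1.0 + 4.0 * np.round((peaks - 1.0) / 4.0)
        assert np.max(np.abs(peaks - analytic)) <= 1.0 / FS + 1e-9

    def test_out_of_band_sinusoid_suppressed(self):
        com, _ = com_sinusoid(5.0)
        resp = isolate_respiration(com, detect_extrema=False)
        assert np.max(np.abs(resp.com_resp_x[1000:-1000])) <= 0.01

    def test_too_short_signal_errors(self):
        from bedposture.features import CoMSeries
        com = CoMSeries(FS, np.zeros(10), np.zeros(10))
        with pytest.raises(ValidationError, match="too short"):
            isolate_respiration(com)


class TestCardiacFilter:
    def test_zero_in_zero_out(self):
        rec = recording_from(*(np.zeros(6000) for _ in range(4)))
        out = isolate_cardiac(rec)
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_in_band_preserved_zero_phase(self):
        t = np.arange(int(120 * FS)) / FS
        s = 0.5 * np.sin(2 * np.pi * 1.2 * t)
        rec = recording_from(100 + s, 100 + s, np.full_like(s, 100), np.full_like(s, 100))
        out = isolate_cardiac(rec)  # LH+RH carries amplitude 1.0 at 1.2 Hz
        mid = slice(2500, -2500)
        assert np.max(np.abs(out[mid])) >= 0.9
        # zero phase: output peaks align with input peaks within one sample
        peak_idx = 2500 + np.argmax(out[mid])
        in_peaks = (np.arange(200) + 0.25) / 1.2  # t where sin(2*pi*1.2 t)=1
        assert np.min(np.abs(t[peak_idx] - in_peaks)) <= 1.0 / FS + 1e-9

    def test_drift_rejected(self):
        t = np.arange(int(120 * FS)) / FS
        drift = np.sin(2 * np.pi * 0.05 * t)
        rec = recording_from(100 + drift, 100 + drift,
                             np.full_like(drift, 100), np.full_like(drift, 100))
        out = isolate_cardiac(rec)
        assert np.max(np.abs(out[2500:-2500])) <= 0.02 * 2.0


# ---------------------------------------------------------------------------
# Breath extrema and angles
# ---------------------------------------------------------------------------

class TestBreathExtrema:
    def test_quarter_hz_sinusoid_yields_15_maxima(self):
        t = np.arange(int(60 * FS)) / FS
        resp = RespSeries(FS, np.sin(2 * np.pi * 0.25 * t), np.zeros_like(t))
        t_max, t_min = detect_breath_extrema(resp)
        assert len(t_max) == 15
        np.testing.assert_allclose(np.diff(t_max), 4.0, atol=1.0 / FS + 1e-9)

    def test_constant_signal_has_no_extrema(self):
        resp = RespSeries(FS, np.full(1000, 3.3), np.full(1000, 1.1))
        t_max, t_min = detect_breath_extrema(resp)
        assert len(t_max) == 0 and len(t_min) == 0

    def test_noisy_sinusoid_after_filtering(self):
        from bedposture.features import CoMSeries
        rng = np.random.default_rng(5)
        t = np.arange(int(120 * FS)) / FS
        x = np.sin(2 * np.pi * 0.25 * t) + rng.normal(0, 0.01, len(t))
        resp = isolate_respiration(CoMSeries(FS, x, np.zeros_like(x)))
        intervals = np.diff(resp.t_max[(resp.t_max > 10) & (resp.t_max < 110)])
        assert np.all(np.abs(intervals - 4.0) <= 0.2)


class TestRespAngle:
    @pytest.mark.parametrize("ax, ay, expected", [
        (1.0, 1.0, 45.0),
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 90.0),
        (1.0, np.sqrt(3.0), 60.0),
    ])
    def test_axis_angle_from_displacement(self, ax, ay, expected):
        t = np.arange(int(20 * FS)) / FS
        s = np.sin(2 * np.pi * 0.25 * t)
        resp = RespSeries(FS, ax * s, ay * s)
        resp.t_max, resp.t_min = detect_breath_extrema(resp)
        angles = resp_angle(resp)
        assert np.isfinite(angles).sum() >= 3
        np.testing.assert_allclose(angles[np.isfinite(angles)], expected, atol=1e-6)

    def test_zero_displacement_pairs_skipped(self):
        resp = RespSeries(FS, np.zeros(100), np.zeros(100),
                          t_max=np.array([0.5]), t_min=np.array([1.0]))
        angles = resp_angle(resp)
        assert not np.isfinite(angles).any()


# ---------------------------------------------------------------------------
# Window features
# ---------------------------------------------------------------------------

class TestExtractFeatures:
    def test_window_count_and_size(self, short_recording):
        rec, _ = short_recording
        table = extract_features(rec)
        # 120 s at 45/15 -> floor((120-45)/15)+1 = 6 windows of 2250 samples
        assert len(table) == 6
        assert int(round(45.0 * rec.sample_rate)) == 2250
        np.testing.assert_allclose(np.diff(table["window_start_s"]), 15.0)

    def test_every_row_has_twelve_features(self, short_recording):
        rec, _ = short_recording
        table = extract_features(rec)
        assert list(table.columns[1:13]) == FEATURE_NAMES
        assert table[FEATURE_NAMES].notna().to_numpy().all()
        assert not table["flag"].any()

    def test_deterministic(self, short_recording):
        rec, _ = short_recording
        a = extract_features(rec)
        b = extract_features(rec)
        np.testing.assert_array_equal(a[FEATURE_NAMES].to_numpy(),
                                      b[FEATURE_NAMES].to_numpy())

    def test_recording_shorter_than_window_rejected(self):
        rec = recording_from(*(np.full(100, 100.0) for _ in range(4)))
        with pytest.raises(ValidationError, match="shorter than one"):
            extract_features(rec)

    def test_uniform_offset_rescales_means_and_leaves_shape_features(self, short_recording):
        """Adding a constant to all channels scales the CoM by W/(W+4c):
        means and stds rescale exactly; angles, ratios and normalised rms
        are scale-free and must not move."""
        rec, _ = short_recording
        c = 25.0
        shifted = recording_from(rec.lh + c, rec.rh + c, rec.lf + c, rec.rf + c,
                                 rec.geometry.width_m, rec.geometry.length_m)
        t1, t2 = extract_features(rec), extract_features(shifted)
        w_total = float(rec.total_force()[0])
        scale = w_total / (w_total + 4 * c)
        for col in ("meanCoM_x", "meanCoM_y", "stdCoM_x", "stdCoM_y"):
            np.testing.assert_allclose(t2[col], t1[col] * scale, rtol=1e-9)
        for col in ("CoM_resp_ANG", "stdCoM_resp_ANG", "ratio_meanCoM", "ratio_stdCoM",
                    "rmsCoM_resp_x", "rmsCoM_resp_y", "ratio_rmsCoM_resp", "rmsPulse"):
            np.testing.assert_allclose(t2[col], t1[col], atol=1e-6, rtol=1e-6)

    def test_feature_csv_round_trip_with_missing(self, tmp_path, short_recording):
        rec, _ = short_recording
        table = extract_features(rec)
        table.loc[0, "CoM_resp_ANG"] = np.nan
        path = write_feature_table(table, tmp_path / "f.csv")
        back = read_feature_table(path)
        assert bool(back.loc[0, "flag"])
        np.testing.assert_allclose(back["meanCoM_x"], table["meanCoM_x"], atol=1e-9)


def test_filterspec_json_round_trip(tmp_path):
    spec = FilterSpec(resp_stop_hz=0.8, resp_order=6, cardiac_band_hz=(1.0, 3.0),
                      rms_norm="none")
    path = spec.to_json(tmp_path / "spec.json")
    assert FilterSpec.from_json(path) == spec


def test_filterspec_rejects_unknown_norm():
    with pytest.raises(ValidationError):
        FilterSpec(rms_norm="p50")
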