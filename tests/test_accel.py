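"""Signal processing: calibration, ENMO, non-wear, sleep, summaries."""

import numpy as np
import pandas as pd
import pytest

from coda24 import (
    AccelConfig,
    DEFAULT_PARTS,
    TriaxialRecording,
    autocalibrate,
    classify_epochs,
    derive_compositions,
    detect_nonwear,
    detect_sleep_windows,
    epoch_enmo,
    filter_valid,
    impute_nonwear,
    process_recording,
    summarize_days,
)
from coda24.accel import CalibrationResult, SleepWindow
from coda24.simulate import (
    distort_recording,
    make_stationary_recording,
    render_triaxial,
    render_week,
)

START = pd.Timestamp("2023-11-06")


def rec_from_constant(vec, hours=1.0, fs=5.0):
    n = int(hours * 3600 * fs)
    return TriaxialRecording("c", START, fs, np.tile(np.asarray(vec, float), (n, 1)))


def manual_schedule(rows):
    df = pd.DataFrame(
        rows, columns=["start_min", "duration_min", "behaviour", "target_enmo_mg", "z_angle_deg"]
    )
    df["azimuth_deg"] = 30.0
    return df


def wake_rows(rng, t0, t1, behaviour="sb", target=30.0, step=15):
    return [
        (t, min(step, t1 - t), behaviour, target, rng.uniform(-45, 45))
        for t in range(t0, t1, step)
    ]


class TestEpochEnmo:
    @pytest.mark.parametrize(
        "vec,expected_mg",
        [((0, 0, 1), 0.0), ((0, 0, 1.2), 200.0), ((0.6, 0, 0.8), 0.0)],
    )
    def test_closed_forms(self, vec, expected_mg):
        out = epoch_enmo(rec_from_constant(vec))
        np.testing.assert_allclose(out["enmo_mg"], expected_mg, atol=1e-9)

    def test_negatives_truncated(self):
        out = epoch_enmo(rec_from_constant((0, 0, 0.9)))
        np.testing.assert_allclose(out["enmo_mg"], 0.0)

    def test_five_second_grid(self):
        out = epoch_enmo(rec_from_constant((0, 0, 1), hours=0.5))
        assert (out.index[1] - out.index[0]).total_seconds() == 5
        assert len(out) == 360


class TestAutocalibrate:
    def test_clean_input_recovers_identity(self):
        rec = make_stationary_recording(sample_rate_hz=5, seed=1)
        _, calib = autocalibrate(rec)
        assert not calib.identity_fallback
        np.testing.assert_allclose(calib.offset_g, 0, atol=2e-3)
        np.testing.assert_allclose(calib.gain, 1, atol=2e-3)
        assert calib.error_mg < 3

    def test_injected_offset_recovered(self):
        rec = make_stationary_recording(sample_rate_hz=5, seed=2)
        bad = distort_recording(rec, offset_mg=(20.0, 0, 0))
        _, calib = autocalibrate(bad)
        # correction offset inverts the +20 mg distortion
        assert calib.offset_g[0] * 1000 == pytest.approx(-20.0, abs=2.0)
        assert calib.error_mg < 10

    def test_injected_gain_recovered(self):
        rec = make_stationary_recording(sample_rate_hz=5, seed=3)
        bad = distort_recording(rec, gain=(1.0, 1.0, 1.05))
        _, calib = autocalibrate(bad)
        assert 1.0 / calib.gain[2] == pytest.approx(1.05, abs=0.005)

    def test_no_stationary_windows_identity_fallback(self):
        rng = np.random.default_rng(0)
        n = int(13 * 3600 * 5)
        data = np.clip(rng.normal(0, 0.4, (n, 3)), -8, 8)
        rec = TriaxialRecording("noisy", START, 5.0, data)
        out, calib = autocalibrate(rec)
        assert calib.identity_fallback
        np.testing.assert_array_equal(out.data, rec.data)

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            autocalibrate(rec_from_constant((0, 0, 1), hours=2))


class TestDetectNonwear:
    def test_static_block_inside_active_day_flagged(self, rng):
        rows = wake_rows(rng, 0, 600, "lpa", 100.0)
        rows += [(600, 120, "nonwear", 0.0, 30.0)]
        rows += wake_rows(rng, 720, 1440, "lpa", 100.0)
        rec = render_triaxial(manual_schedule(rows), sample_rate_hz=5, seed=4)
        worn = detect_nonwear(rec)
        flagged = (~worn).sum() * 5 / 60  # minutes
        epm = 12
        inside = (~worn.iloc[600 * epm : 720 * epm]).sum() * 5 / 60
        assert inside >= 60
        assert flagged == inside  # no false flags outside the gap

    def test_continuous_activity_not_flagged(self, rng):
        rows = wake_rows(rng, 0, 1440, "mvpa", 250.0)
        rec = render_triaxial(manual_schedule(rows), sample_rate_hz=5, seed=5)
        assert detect_nonwear(rec).all()

    def test_sd_boundary_is_strict(self):
        # alternating +/-a on every axis gives a per-window SD of exactly a;
        # a = 2^-6 g keeps every intermediate exact in binary floating point,
        # so SD == threshold exercises the strict < of the rule
        a = 2.0**-6
        cfg = AccelConfig(nonwear_sd_mg=a * 1000, nonwear_range_mg=0.0)  # SD rule only
        n = int(2 * 3600 * 5)
        pattern = np.tile([a, -a], n // 2)[:, None] * np.ones(3)
        rec = TriaxialRecording("b", START, 5.0, pattern + [0, 0, 1.0])
        assert detect_nonwear(rec, cfg).all()
        shrunk = TriaxialRecording("b", START, 5.0, pattern * 0.99 + [0, 0, 1.0])
        assert not detect_nonwear(shrunk, cfg).all()

    def test_mid_variability_not_flagged_by_either_rule(self):
        # SD 26 mg and range 52 mg: fails both criteria, stays worn
        n = int(2 * 3600 * 5)
        pattern = np.tile([26e-3, -26e-3], n // 2)[:, None] * np.ones(3)
        rec = TriaxialRecording("b", START, 5.0, pattern + [0, 0, 1.0])
        assert detect_nonwear(rec).all()


class TestImpute:
    def _epochs(self):
        idx = pd.date_range(START, periods=2 * 17280, freq="5s")
        enmo = np.full(len(idx), 40.0)
        worn = np.ones(len(idx), dtype=bool)
        return pd.DataFrame({"enmo_mg": enmo, "worn": worn}, index=idx)

    def test_slot_mean_of_other_days(self):
        ep = self._epochs()
        ep.iloc[:720, ep.columns.get_loc("enmo_mg")] = 30.0  # day 1 values
        ep.iloc[17280 : 17280 + 720, ep.columns.get_loc("enmo_mg")] = 60.0
        ep.iloc[:720, ep.columns.get_loc("worn")] = False  # day-1 morning off body
        out = impute_nonwear(ep)
        # imputed from the only other day at those clock slots -> 60
        np.testing.assert_allclose(out["enmo_mg"].iloc[:720], 60.0)
        assert out["imputed"].iloc[:720].all()

    def test_fully_worn_identity(self):
        ep = self._epochs()
        out = impute_nonwear(ep)
        np.testing.assert_allclose(out["enmo_mg"], ep["enmo_mg"])
        assert not out["imputed"].any()

    def test_never_worn_slot_uses_overall_mean(self):
        ep = self._epochs()
        ep.iloc[:720, ep.columns.get_loc("worn")] = False
        ep.iloc[17280 : 17280 + 720, ep.columns.get_loc("worn")] = False
        with pytest.warns(UserWarning):
            out = impute_nonwear(ep)
        np.testing.assert_allclose(out["enmo_mg"].iloc[:720], 40.0)


class TestSleepDetection:
    def _render_day(self, rows, fs=5.0, seed=6):
        return render_triaxial(manual_schedule(rows), sample_rate_hz=fs, seed=seed)

    def test_single_still_bout_recovered(self, rng):
        rows = wake_rows(rng, 0, 780, "lpa", 100.0)
        rows += [(780, 160, "sleep", 10.0, 45.0), (940, 160, "sleep", 10.0, 60.0),
                 (1100, 160, "sleep", 10.0, 40.0)]
        rows += wake_rows(rng, 1260, 1440, "sb", 30.0)
        rec = self._render_day(rows)
        windows = [w for w in detect_sleep_windows(rec) if w.valid]
        assert len(windows) == 1
        assert windows[0].duration_min == pytest.approx(480, abs=15)

    def test_longest_block_selected(self, rng):
        rows = wake_rows(rng, 0, 720, "lpa", 100.0)
        rows += [(720, 100, "sleep", 10.0, 50.0)]
        rows += wake_rows(rng, 820, 1000, "mvpa", 250.0)
        rows += [(1000, 200, "sleep", 10.0, 40.0), (1200, 200, "sleep", 10.0, 55.0)]
        rows += wake_rows(rng, 1400, 1440, "sb", 30.0)
        rec = self._render_day(rows)
        w = max((w for w in detect_sleep_windows(rec) if w.valid), key=lambda w: w.duration_min)
        assert w.duration_min == pytest.approx(400, abs=15)
        assert w.onset.hour in (16, 17)  # the 400-min block, not the 100-min one

    def test_constant_angle_degenerate_capped(self):
        rows = [(0, 1440, "nonwear", 0.0, 30.0)]
        rec = render_triaxial(manual_schedule(rows), sample_rate_hz=5, seed=7, noise_sd_mg=0.0)
        windows = detect_sleep_windows(rec)
        assert all((not w.valid) for w in windows)
        assert any(w.capped for w in windows)


class TestClassify:
    def _epochs(self, enmo):
        idx = pd.date_range(START, periods=len(enmo), freq="5s")
        return pd.DataFrame({"enmo_mg": enmo}, index=idx)

    def test_cutpoint_boundaries(self):
        out = classify_epochs(self._epochs([40.0, 50.0, 51.0, 199.9, 200.0, 500.0]), [])
        assert list(out["label"]) == ["sb", "sb", "lpa", "lpa", "mvpa", "mvpa"]

    def test_sleep_window_overrides_intensity(self):
        ep = self._epochs([100.0, 100.0, 100.0])
        win = SleepWindow(0, ep.index[1], ep.index[2])
        out = classify_epochs(ep, [win])
        assert list(out["label"]) == ["lpa", "sleep", "lpa"]

    def test_invalid_window_ignored(self):
        ep = self._epochs([100.0] * 3)
        win = SleepWindow(0, ep.index[0], ep.index[-1], valid=False, capped=True)
        assert (classify_epochs(ep, [win])["label"] == "lpa").all()

    def test_monotone_in_enmo(self, rng):
        """Raising ENMO never lowers the intensity class."""
        order = {"sb": 0, "lpa": 1, "mvpa": 2}
        e = np.sort(rng.uniform(0, 400, 200))
        labels = classify_epochs(self._epochs(e), [])["label"].map(order).to_numpy()
        assert (np.diff(labels) >= 0).all()


class TestSummariesAndFiltering:
    def _labelled_day(self, date="2023-11-06"):
        idx = pd.date_range(date, periods=17280, freq="5s")
        labels = np.array(["sb"] * 17280, dtype=object)
        labels[: 480 * 12] = "sleep"
        return pd.DataFrame({"label": labels, "worn": True, "enmo_mg": 20.0}, index=idx)

    def test_pure_sb_day_with_sleep(self):
        days = summarize_days(self._labelled_day())
        r = days.iloc[0]
        assert (r["sleep_min"], r["sb_min"], r["lpa_min"], r["mvpa_min"]) == (480, 960, 0, 0)
        assert r["day_type"] == "weekday"

    def test_minutes_conservation_and_school_segment(self):
        days = summarize_days(self._labelled_day())
        r = days.iloc[0]
        assert r[["sleep_min", "sb_min", "lpa_min", "mvpa_min"]].sum() == 1440
        school = r[["school_sleep_min", "school_sb_min", "school_lpa_min", "school_mvpa_min"]]
        assert school.sum() == 390

    def test_partial_days_dropped(self):
        df = self._labelled_day()
        days = summarize_days(df.iloc[100:])
        assert days.empty

    def _days(self, n_valid, n_short=0):
        rows = []
        for i in range(n_valid + n_short):
            rows.append(
                {
                    "date": pd.Timestamp("2023-11-06") + pd.Timedelta(days=i),
                    "day_type": "weekday" if i < 5 else "weekend",
                    "wear_h": 20.0 if i < n_valid else 10.0,
                    "sleep_min": 400.0 + 40 * (i % 2),
                    "sb_min": 700.0 - 40 * (i % 2),
                    "lpa_min": 270.0,
                    "mvpa_min": 70.0,
                    "school_sb_min": 300.0,
                    "school_lpa_min": 70.0,
                    "school_mvpa_min": 20.0,
                    "school_sleep_min": 0.0,
                }
            )
        return pd.DataFrame(rows)

    def test_three_valid_days_excluded(self):
        included, _ = filter_valid(self._days(3, 4))
        assert not included

    def test_calibration_error_boundary(self):
        ok = CalibrationResult(np.zeros(3), np.ones(3), 10.0, 50)
        bad = CalibrationResult(np.zeros(3), np.ones(3), 12.0, 50)
        assert filter_valid(self._days(4), ok)[0]
        assert not filter_valid(self._days(7), bad)[0]

    def test_derive_total_mean_of_days(self):
        _, valid = filter_valid(self._days(2))
        comp = derive_compositions(valid, "total")
        assert comp["sleep"] == pytest.approx(420.0)
        assert comp.sum() == pytest.approx(1440.0)

    def test_derive_school_three_part(self):
        _, valid = filter_valid(self._days(5))
        comp = derive_compositions(valid, "school")
        assert list(comp.index) == ["sb", "lpa", "mvpa"]
        assert comp.sum() == pytest.approx(390.0)

    def test_missing_segment_returns_none(self):
        _, valid = filter_valid(self._days(4))  # weekdays only
        assert derive_compositions(valid, "weekend") is None


class TestCsvRoundTrip:
    def test_recording_survives_csv(self, tmp_path, rng):
        data = np.clip(rng.normal([0, 0, 1], 0.05, (600, 3)), -8, 8)
        rec = TriaxialRecording("P1", START, 20.0, data)
        path = tmp_path / "signal_P1.csv"
        rec.to_csv(path)
        back = TriaxialRecording.from_csv(path, participant="P1")
        assert back.sample_rate_hz == pytest.approx(20.0)
        assert back.start == rec.start
        np.testing.assert_allclose(back.data, rec.data, atol=1e-5)  # 5-dp CSV


class TestEndToEnd:
    def test_two_day_recovery(self):
        minutes = {"sleep": 450.0, "sb": 690.0, "lpa": 230.0, "mvpa": 70.0}
        rec, _, _ = render_week(minutes, days=2, sample_rate_hz=10, seed=21)
        out = process_recording(rec, calibrate=False)
        days = out["days"]
        assert len(days) == 2
        for p in DEFAULT_PARTS:
            np.testing.assert_allclose(days[f"{p}_min"], minutes[p], atol=2.0)
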