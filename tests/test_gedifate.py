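"""GEDI ratios, tracking, threshold calibration, fate calling and survival."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from radassay import gedifate as gf, synthgen as sg
from radassay.gedifate import CalibrationError, CellTrack


def make_track(ratios, present=None, timepoints=(0.0, 6.0, 12.0, 18.0),
               group="g", track_id=0, first_seen=None, red=500.0):
    ratios = np.asarray(ratios, dtype=float)
    tp = np.asarray(timepoints, dtype=float)[: len(ratios)]
    if present is None:
        present = np.isfinite(ratios)
    present = np.asarray(present, dtype=bool)
    mean_red = np.where(present, red, np.nan)
    mean_green = np.where(present, red * ratios, np.nan)
    return CellTrack(
        track_id=track_id, group=group, timepoints_h=tp, present=present,
        mean_red=mean_red, mean_green=mean_green,
        first_seen_h=first_seen if first_seen is not None else tp[present][0],
    )


def object_table(labels, rows, cols, red=500.0, green=250.0):
    n = len(labels)
    return pd.DataFrame(
        {
            "label": labels,
            "centroid_row": rows,
            "centroid_col": cols,
            "mean_red": [red] * n if np.isscalar(red) else red,
            "mean_green": [green] * n if np.isscalar(green) else green,
        }
    )


class TestGediRatio:
    @pytest.mark.parametrize(
        "green,red,expected",
        [(500.0, 500.0, 1.0), (0.0, 400.0, 0.0), (176.0, 100.0, 1.76)],
    )
    def test_examples(self, green, red, expected):
        assert gf.gedi_ratio(green, red) == pytest.approx(expected)

    def test_unmeasurable_red_gives_nan(self):
        assert np.isnan(gf.gedi_ratio(100.0, 5.0, red_floor=10.0))
        out = gf.gedi_ratio(np.array([100.0, 100.0]), np.array([5.0, 50.0]), 10.0)
        assert np.isnan(out[0]) and out[1] == pytest.approx(2.0)

    @given(
        green=st.floats(0.1, 1e4),
        red=st.floats(0.1, 1e4),
        gain=st.floats(0.01, 100.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_common_gain_invariance(self, green, red, gain):
        base = gf.gedi_ratio(green, red)
        scaled = gf.gedi_ratio(gain * green, gain * red)
        assert scaled == pytest.approx(base, rel=1e-9)

    @given(green=st.floats(0.1, 1e4), red=st.floats(0.1, 1e4),
           gain=st.floats(0.01, 100.0))
    @settings(deadline=None, max_examples=100)
    def test_linear_in_green_gain(self, green, red, gain):
        assert gf.gedi_ratio(gain * green, red) == pytest.approx(
            gain * gf.gedi_ratio(green, red), rel=1e-9
        )


class TestTrackCells:
    def test_single_static_cell(self):
        tables = {
            t: object_table([1], [50.0], [60.0]) for t in (0.0, 6.0, 12.0, 18.0)
        }
        tracks = gf.track_cells(tables, max_displacement_px=10)
        assert len(tracks) == 1
        assert tracks[0].present.all()
        assert tracks[0].first_seen_h == 0.0

    def test_two_distant_cells_never_swap(self):
        tables = {}
        for k, t in enumerate((0.0, 6.0)):
            tables[t] = object_table(
                [1, 2], [10.0 + k, 200.0 - k], [10.0, 200.0],
                red=[400.0, 800.0],
            )
        tracks = gf.track_cells(tables, max_displacement_px=20)
        assert len(tracks) == 2
        for tr in tracks:
            assert np.ptp(tr.mean_red[tr.present]) == 0  # identity preserved

    def test_jump_terminates_track_and_opens_new(self):
        tables = {
            0.0: object_table([1], [10.0], [10.0]),
            6.0: object_table([1], [100.0], [100.0]),  # > max_displacement away
        }
        tracks = gf.track_cells(tables, max_displacement_px=15)
        assert len(tracks) == 2
        old = next(t for t in tracks if t.first_seen_h == 0.0)
        new = next(t for t in tracks if t.first_seen_h == 6.0)
        assert list(old.present) == [True, False]
        assert list(new.present) == [False, True]

    def test_duplicate_labels_rejected(self):
        tables = {0.0: object_table([1, 1], [5.0, 50.0], [5.0, 50.0])}
        with pytest.raises(ValueError, match="duplicate"):
            gf.track_cells(tables)

    def test_recovers_truth_identity_with_jitter(self, timelapse_small):
        from radassay import imgseg

        params, frames, truth = timelapse_small
        tables = {f.timepoint_h: imgseg.segment_cells_red(f).table for f in frames}
        tracks = gf.track_cells(tables, max_displacement_px=12)
        baseline = [t for t in tracks if t.first_seen_h == 0.0]
        # red amplitude is constant per cell: its mask-mean varies only noise-wise
        for tr in baseline:
            reds = tr.mean_red[tr.present]
            assert reds.std() / reds.mean() < 0.15


class TestCalibrateThreshold:
    def test_fully_separated_midpoint(self):
        res = gf.calibrate_threshold([0.5] * 10, [1.5] * 10)
        assert res.theta == pytest.approx(1.0)
        assert res.misclassification_rate == 0.0

    def test_identical_samples_fail(self):
        with pytest.raises(CalibrationError):
            gf.calibrate_threshold([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0.6, 0.2, 1000)
        lethal = rng.normal(1.4, 0.2, 1000)
        res = gf.calibrate_threshold(base, lethal)

        # oracle: evaluate misclassification at every sorted sample value
        cand = np.sort(np.concatenate([base, lethal]))
        errs = np.array(
            [((base > c).sum() + (lethal <= c).sum()) / 2000 for c in cand]
        )
        oracle = cand[np.argmin(errs)]
        assert abs(res.theta - oracle) <= 0.05
        assert res.misclassification_rate <= errs.min() + 1e-12

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            gf.calibrate_threshold([], [1.0])


class TestCallFates:
    def test_ratio_crossing_event(self):
        # ratio course of an untreated dying cell: crosses theta=1 at 12 h
        track = make_track([0.5, 0.6, 1.76], timepoints=(0.0, 6.0, 12.0))
        fates = gf.call_fates([track], theta=1.0)
        rec = fates.iloc[0]
        assert rec.status == "event" and rec.cause == "ratio_crossing"
        assert rec.time_h == 12.0

    def test_surviving_cell_censored_at_end(self):
        track = make_track([0.5, 0.6, 0.7, 0.8])
        rec = gf.call_fates([track], theta=1.0).iloc[0]
        assert rec.status == "censored" and rec.cause == "none"
        assert rec.time_h == 18.0

    def test_disappearance_is_death(self):
        track = make_track([0.5, 0.6, np.nan, np.nan])
        rec = gf.call_fates([track], theta=1.0).iloc[0]
        assert rec.status == "event" and rec.cause == "disappearance"
        assert rec.time_h == 12.0

    def test_crossing_before_disappearance_wins(self):
        track = make_track([0.5, 1.4, np.nan, np.nan])
        rec = gf.call_fates([track], theta=1.0).iloc[0]
        assert rec.cause == "ratio_crossing" and rec.time_h == 6.0

    def test_disappearance_only_mode(self):
        track = make_track([0.5, 1.4, 1.5, 1.6])
        rec = gf.call_fates([track], theta=1.0, events="disappearance").iloc[0]
        assert rec.status == "censored"

    def test_infinite_theta_no_disappearance_all_censored(self):
        tracks = [make_track([0.5, 2.0, 3.0, 4.0], track_id=i) for i in range(5)]
        fates = gf.call_fates(tracks, theta=1e12)
        assert (fates["status"] == "censored").all()

    def test_late_appearing_track_excluded(self):
        late = make_track([np.nan, 0.5, 0.5, 0.5], first_seen=6.0)
        fates = gf.call_fates([late], theta=1.0)
        assert len(fates) == 0

    def test_unmeasurable_track_warns_and_excluded(self):
        track = make_track([0.5, 0.5], timepoints=(0.0, 6.0), red=0.0)
        with pytest.warns(UserWarning, match="no measurable"):
            fates = gf.call_fates([track], theta=1.0, red_floor=10.0)
        assert len(fates) == 0

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            gf.call_fates([], theta=0.0)


def fates_frame(times, statuses, group="g"):
    return pd.DataFrame(
        {
            "track_id": range(len(times)),
            "group": group,
            "time_h": times,
            "status": statuses,
            "cause": ["ratio_crossing" if s == "event" else "none" for s in statuses],
        }
    )


class TestKmCurve:
    def test_hand_product_limit(self):
        fates = fates_frame([6, 12, 18, 18], ["event", "event", "event", "censored"])
        curve = gf.km_curve(fates)
        assert curve.survival_at(6) == pytest.approx(0.75)
        assert curve.survival_at(12) == pytest.approx(0.50)
        assert curve.survival_at(18) == pytest.approx(0.25)
        assert curve.survival_at(0) == 1.0

    def test_no_events_flat_one(self):
        fates = fates_frame([18, 18, 18, 18], ["censored"] * 4)
        curve = gf.km_curve(fates)
        assert np.allclose(curve.survival, 1.0)

    def test_all_events_at_first_timepoint(self):
        fates = fates_frame([6, 6, 6], ["event"] * 3)
        assert gf.km_curve(fates).survival_at(6) == 0.0

    def test_monotone_in_unit_interval_random(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = rng.integers(3, 40)
            times = rng.choice([6.0, 12.0, 18.0], n)
            statuses = rng.choice(["event", "censored"], n)
            if (statuses == "event").sum() == 0:
                statuses[0] = "event"
            curve = gf.km_curve(fates_frame(times, statuses))
            assert np.all(curve.survival >= 0) and np.all(curve.survival <= 1)
            assert np.all(np.diff(curve.survival) <= 1e-12)
            assert np.all(np.diff(curve.at_risk) <= 0)

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(7)
        times = rng.choice([6.0, 12.0, 18.0, 24.0], 50)
        curve = gf.km_curve(fates_frame(times, ["event"] * 50))
        for t in (6.0, 12.0, 18.0, 24.0):
            assert curve.survival_at(t) == pytest.approx((times > t).mean())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gf.km_curve(fates_frame([], []))


class TestLogrank:
    def test_identical_event_times_statistic_zero(self):
        a = fates_frame([6, 12, 18], ["event"] * 3, group="a")
        b = fates_frame([6, 12, 18], ["event"] * 3, group="b")
        res = gf.logrank(pd.concat([a, b], ignore_index=True))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_matches_independent_implementation(self):
        rng = np.random.default_rng(3)
        times = np.concatenate([rng.exponential(8, 30), rng.exponential(16, 30)])
        times = np.round(times / 6) * 6 + 6
        events = rng.random(60) < 0.8
        fates = pd.DataFrame(
            {
                "track_id": range(60),
                "group": ["a"] * 30 + ["b"] * 30,
                "time_h": times,
                "status": np.where(events, "event", "censored"),
                "cause": "none",
            }
        )
        res = gf.logrank(fates, pairwise=False)
        # independently coded O-E / hypergeometric-variance statistic
        grp = np.array([True] * 30 + [False] * 30)
        o_e, var = 0.0, 0.0
        for u in np.unique(times[events]):
            at = times >= u
            n, n1 = at.sum(), (at & grp).sum()
            d = ((times == u) & events).sum()
            d1 = ((times == u) & events & grp).sum()
            o_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        assert res.statistic == pytest.approx(o_e**2 / var, rel=1e-9)

    def test_no_events_undefined(self):
        a = fates_frame([18], ["censored"], group="a")
        b = fates_frame([18], ["censored"], group="b")
        with pytest.raises(ValueError, match="no events"):
            gf.logrank(pd.concat([a, b], ignore_index=True))

    def test_pairwise_against_control_with_bonferroni(self):
        rng = np.random.default_rng(5)
        frames = []
        for g, lam in (("control", 0.15), ("low", 0.08), ("high", 0.04)):
            t = np.ceil(rng.exponential(1 / lam, 80) / 6) * 6
            ev = t <= 18
            frames.append(
                fates_frame(np.minimum(t, 18),
                            np.where(ev, "event", "censored"), group=g)
            )
        fates = pd.concat(frames, ignore_index=True)
        res = gf.logrank(fates, control="control")
        assert set(res.pairwise["group_b"]) == {"low", "high"}
        assert (res.pairwise["p_bonferroni"] >= res.pairwise["p_value"] - 1e-15).all()
        assert "chi2" in res.summary()

    def test_dose_monotonic_survival(self):
        """Lower hazard gives stochastically later events, hence higher S(t)
        at every scheduled timepoint (n=500/arm, fixed seed)."""
        rng = np.random.default_rng(2024)
        curves = {}
        for g, h in (("control", 0.12), ("low", 0.08), ("high", 0.04)):
            death = sg.sample_death_times(h, 500, rng)
            cells = pd.DataFrame(
                {
                    "cell_id": np.arange(500),
                    "group": g,
                    "death_time_h": death,
                    "detach_time_h": np.nan,
                    "red_amp": 500.0,
                }
            )
            tracks = sg.tracks_from_truth(sg.GroundTruth(cells=cells))
            curves[g] = gf.km_curve(gf.call_fates(tracks, theta=1.0))
        for t in (6.0, 12.0, 18.0):
            assert (
                curves["control"].survival_at(t)
                < curves["low"].survival_at(t)
                < curves["high"].survival_at(t)
            )
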