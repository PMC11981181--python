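import math

import numpy as np
import pytest

from drawscreen import features as ft
from drawscreen import recording_io as rio
from tests.test_recording_io import make_recording


class TestPressure:
    def test_constant_pressure(self):
        m, sd, ch = ft.pressure_features([np.full(20, 0.5)])
        assert (m, sd, ch) == (0.5, 0.0, 0.0)

    def test_three_sample_ramp(self):
        m, sd, ch = ft.pressure_features([np.array([0.2, 0.4, 0.6])])
        assert m == pytest.approx(0.4)
        assert sd == pytest.approx(0.2)
        assert ch == pytest.approx(0.2)

    def test_no_change_across_segment_boundary(self):
        m, sd, ch = ft.pressure_features([np.array([0.2, 0.4]), np.array([0.8, 0.6])])
        assert m == pytest.approx(0.5)
        assert ch == pytest.approx(0.2)  # the 0.4 -> 0.8 jump is never differenced

    def test_insufficient_data(self):
        with pytest.raises(ft.InsufficientDataError):
            ft.pressure_features([np.array([0.5])])


class TestKinematics:
    def test_constant_velocity_line(self):
        n = 30
        t = np.arange(n) / 30.0
        x = np.arange(n) * 0.01  # 0.01 screen units per frame at 30 Hz
        y = np.full(n, 0.5)
        m, sd, acc = ft.kinematics_features([(x, y)], [t])
        assert m == pytest.approx(0.01 * 30)  # 0.3 units/s
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert acc == pytest.approx(0.0, abs=1e-12)

    def test_speed_change_sequence(self):
        # construct positions so per-pair speeds are exactly [1, 2, 3] units/s
        t = np.array([0.0, 1.0, 2.0, 3.0])
        x = np.cumsum([0.0, 1.0, 2.0, 3.0]) / 10  # distances 0.1, 0.2, 0.3 per 1 s
        y = np.zeros(4)
        m, sd, acc = ft.kinematics_features([(x, y)], [t])
        assert m == pytest.approx(0.2)
        assert acc == pytest.approx(0.1)

    def test_stationary_pen_down(self):
        t = np.arange(10) / 30.0
        x = np.full(10, 0.4)
        y = np.full(10, 0.6)
        m, sd, acc = ft.kinematics_features([(x, y)], [t])
        assert (m, sd, acc) == (0.0, 0.0, 0.0)


class TestPose:
    def test_constant_tilt(self):
        out = ft.pose_features([np.full(10, 45.0)], [np.full(10, 120.0)])
        assert out[0] == pytest.approx(45.0)
        assert out[1] == 0.0
        assert out[2] == 0.0

    def test_orientation_wraparound(self):
        """A 350 deg -> 10 deg step means 20 deg of motion through north."""
        out = ft.pose_features([np.full(2, 45.0)], [np.array([350.0, 10.0])])
        m_azi, sd_azi, ch_azi = out[3], out[4], out[5]
        assert m_azi == pytest.approx(0.0, abs=1e-9) or m_azi == pytest.approx(360.0)
        assert ch_azi == pytest.approx(20.0)

    def test_constant_orientation(self):
        out = ft.pose_features([np.full(5, 45.0)], [np.full(5, 270.0)])
        assert out[3] == pytest.approx(270.0)
        assert out[4] == pytest.approx(0.0, abs=1e-9)

    def test_linear_fallback_mode(self):
        cfg = ft.FeatureConfig(orientation_stats="linear")
        out = ft.pose_features([np.full(2, 45.0)], [np.array([350.0, 10.0])], cfg)
        assert out[3] == pytest.approx(180.0)  # naive arithmetic mean
        assert out[5] == pytest.approx(340.0)  # naive |difference|


class TestGazeCoupling:
    def test_exact_linear_dependence(self):
        x = np.linspace(0.1, 0.9, 50)
        val, ok = ft.gaze_coupling(2 * x - 1, x)
        assert ok and val == pytest.approx(1.0)

    def test_exact_negative_dependence(self):
        x = np.linspace(0.1, 0.9, 50)
        val, ok = ft.gaze_coupling(-x, x)
        assert ok and val == pytest.approx(-1.0)

    def test_constant_gaze_is_invalid(self):
        x = np.linspace(0.1, 0.9, 50)
        val, ok = ft.gaze_coupling(np.full(50, 10.0), x)
        assert not ok and val == 0.0

    def test_too_few_pairs_invalid(self):
        val, ok = ft.gaze_coupling(np.arange(5.0), np.arange(5.0))
        assert not ok

    def test_pairwise_missing_dropped(self):
        x = np.linspace(0.1, 0.9, 40)
        g = 3 * x
        g[::4] = np.nan
        val, ok = ft.gaze_coupling(g, x)
        assert ok and val == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Independent brute-force oracle


def naive_features(segs_p, segs_xy, segs_t, segs_tilt, segs_azi):
    """Definition-level recomputation of the 12 pen features, by loops."""
    out = {}
    pooled = [v for s in segs_p for v in s]
    n = len(pooled)
    mean = sum(pooled) / n
    out["Mpenpressure"] = mean
    out["SDpenpressure"] = math.sqrt(sum((v - mean) ** 2 for v in pooled) / (n - 1))
    diffs = [abs(s[i + 1] - s[i]) for s in segs_p for i in range(len(s) - 1)]
    out["Mpenpressurechange"] = sum(diffs) / len(diffs)

    speeds = []
    for (x, y), t in zip(segs_xy, segs_t):
        for i in range(len(x) - 1):
            d = math.hypot(x[i + 1] - x[i], y[i + 1] - y[i])
            speeds.append(d / (t[i + 1] - t[i]))
    vm = sum(speeds) / len(speeds)
    out["Mdrawingspeed"] = vm
    out["SDdrawingspeed"] = math.sqrt(sum((v - vm) ** 2 for v in speeds) / (len(speeds) - 1))
    accs = []
    k = 0
    for (x, y), t in zip(segs_xy, segs_t):
        seg_sp = speeds[k : k + len(x) - 1]
        k += len(x) - 1
        accs.extend(abs(seg_sp[i + 1] - seg_sp[i]) for i in range(len(seg_sp) - 1))
    out["Mdrawingacceleration"] = sum(accs) / len(accs)

    tilts = [v for s in segs_tilt for v in s]
    tm = sum(tilts) / len(tilts)
    out["Mpentilt"] = tm
    out["SDpentilt"] = math.sqrt(sum((v - tm) ** 2 for v in tilts) / (len(tilts) - 1))
    tdiffs = [abs(s[i + 1] - s[i]) for s in segs_tilt for i in range(len(s) - 1)]
    out["Mpentiltchange"] = sum(tdiffs) / len(tdiffs)

    azis = [v for s in segs_azi for v in s]
    s_sin = sum(math.sin(math.radians(a)) for a in azis) / len(azis)
    s_cos = sum(math.cos(math.radians(a)) for a in azis) / len(azis)
    out["Mpenorientation"] = math.degrees(math.atan2(s_sin, s_cos)) % 360.0
    r = min(math.hypot(s_sin, s_cos), 1.0)
    out["SDpenorientation"] = math.degrees(math.sqrt(-2.0 * math.log(r)))
    adiffs = []
    for s in segs_azi:
        for i in range(len(s) - 1):
            d = (s[i + 1] - s[i] + 180.0) % 360.0 - 180.0
            adiffs.append(abs(d))
    out["Mpenorientationchange"] = sum(adiffs) / len(adiffs)
    return out


@pytest.mark.parametrize("seed", range(8))
def test_oracle_equivalence_on_random_segments(seed):
    """Every pen feature matches a loop-level recomputation to 1e-10."""
    rng = np.random.default_rng(seed)
    n_segs = rng.integers(1, 4)
    segs_p, segs_xy, segs_t, segs_tilt, segs_azi = [], [], [], [], []
    t0 = 0.0
    for _ in range(n_segs):
        m = int(rng.integers(10, 50))
        segs_p.append(rng.uniform(0.05, 0.95, m))
        segs_xy.append((rng.uniform(0, 1, m), rng.uniform(0, 1, m)))
        segs_t.append(t0 + np.arange(m) / 30.0)
        t0 += m / 30.0 + 0.4
        segs_tilt.append(rng.uniform(10, 80, m))
        segs_azi.append(rng.uniform(0, 360, m))
    ref = naive_features(
        [list(s) for s in segs_p],
        [(list(x), list(y)) for x, y in segs_xy],
        [list(t) for t in segs_t],
        [list(s) for s in segs_tilt],
        [list(s) for s in segs_azi],
    )
    mp, sdp, chp = ft.pressure_features(segs_p)
    ms, sds, acc = ft.kinematics_features(segs_xy, segs_t)
    mt, sdt, cht, mo, sdo, cho = ft.pose_features(segs_tilt, segs_azi)
    got = {
        "Mpenpressure": mp, "SDpenpressure": sdp, "Mpenpressurechange": chp,
        "Mdrawingspeed": ms, "SDdrawingspeed": sds, "Mdrawingacceleration": acc,
        "Mpentilt": mt, "SDpentilt": sdt, "Mpentiltchange": cht,
        "Mpenorientation": mo, "SDpenorientation": sdo, "Mpenorientationchange": cho,
    }
    for name, expected in ref.items():
        assert got[name] == pytest.approx(expected, abs=1e-10), name


def test_frame_rate_invariance_on_constant_velocity_path():
    """Halving the frame rate leaves speed and level statistics unchanged."""
    n = 120
    t30 = np.arange(n) / 30.0
    x = 0.1 + np.arange(n) * 0.005
    y = np.full(n, 0.5)
    p = 0.5 + 0.1 * np.sin(np.arange(n) / 20.0)
    m30, _, _ = ft.kinematics_features([(x, y)], [t30])
    m15, _, _ = ft.kinematics_features([(x[::2], y[::2])], [t30[::2]])
    assert m15 == pytest.approx(m30, rel=1e-9)
    p30 = ft.pressure_features([p])[0]
    p15 = ft.pressure_features([p[::2]])[0]
    assert p15 == pytest.approx(p30, rel=0.02)


class TestExtractVector:
    def test_all_gaze_missing_flags_correlations(self):
        drawing = make_recording([0.5] * 60)
        demo = make_recording(
            [0.0] * 60, phase="demo",
            line_x=np.linspace(0.1, 0.9, 60), line_y=np.linspace(0.1, 0.9, 60),
        )
        fv = ft.extract_feature_vector(demo, drawing)
        pen = [n for n in rio.FEATURE_NAMES if not n.startswith("Corr")]
        corr = [n for n in rio.FEATURE_NAMES if n.startswith("Corr")]
        assert all(fv.valid[n] for n in pen)
        assert all(not fv.valid[n] for n in corr)
        assert all(fv.values[n] == 0.0 for n in corr)  # imputed

    def test_no_active_drawing_raises(self):
        drawing = make_recording([0.0] * 40)
        with pytest.raises(ft.NoActiveDrawingError, match="P001"):
            ft.extract_feature_vector(None, drawing)

    def test_batch_extraction_complete(self, default_cohort):
        _, sheets = default_cohort
        for shape, df in sheets.items():
            assert len(df) == 133
            pen = [n for n in rio.FEATURE_NAMES if not n.startswith("Corr")]
            assert not df[pen].isna().any().any()
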