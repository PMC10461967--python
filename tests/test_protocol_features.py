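"""Protocol fixture, window extraction, AP detection and AP features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trace
from ricp.features import ap_features, detect_aps, extract_vc_features
from ricp.protocol import (Segment, TimePointSpec, VCProtocol,
                           ricp_protocol, ricp_timepoints)


class TestTimepoints:
    def test_eight_specs_with_printed_centers(self):
        tps = {tp.label: tp for tp in ricp_timepoints()}
        assert len(tps) == 8
        expected = {
            "I_6mV": (600.0, "avg"), "I_Kr": (1262.0, "avg"),
            "I_CaL": (1986.0, "min"), "I_Na": (2760.0, "min"),
            "I_to": (3641.0, "avg"), "I_K1": (4300.0, "avg"),
            "I_f": (5840.0, "avg"), "I_Ks": (9040.0, "avg"),
        }
        for label, (t, method) in expected.items():
            assert tps[label].t_center == t
            assert tps[label].method == method
            assert tps[label].window == 2.0

    def test_centers_inside_protocol(self, protocol):
        for tp in ricp_timepoints():
            assert 0 <= tp.t_center - 1 and tp.t_center + 1 < \
                protocol.total_duration


class TestProtocolFixture:
    def test_total_duration_is_10s(self, protocol):
        assert protocol.total_duration == 10_000.0

    def test_ikr_subsegment_voltages(self, protocol):
        """750 ms at 6 mV, 7 ms at -41 mV, then up to 9 mV."""
        assert protocol.voltage_at(500.0) == 6.0
        assert protocol.voltage_at(1249.9) == 6.0
        assert protocol.voltage_at(1250.0) == -41.0
        assert protocol.voltage_at(1256.9) == -41.0
        assert protocol.voltage_at(1257.0) == 9.0
        assert protocol.voltage_at(1262.0) == 9.0

    def test_i6mv_step(self, protocol):
        assert protocol.voltage_at(499.9) == -80.0
        assert protocol.voltage_at(500.0) == 6.0
        assert protocol.voltage_at(600.0) == 6.0

    def test_voltage_defined_everywhere(self, protocol):
        t = np.linspace(0.0, protocol.total_duration - 1e-9, 1000)
        v = protocol.voltage_at(t)
        assert np.all(np.isfinite(v))

    def test_roundtrip_csv(self, tmp_path, protocol):
        path = tmp_path / "prot.csv"
        protocol.to_csv(path)
        again = VCProtocol.from_csv(path)
        assert again.total_duration == protocol.total_duration
        t = np.linspace(0, 9999.9, 500)
        np.testing.assert_allclose(again.voltage_at(t),
                                   protocol.voltage_at(t))

    def test_invalid_segments_rejected(self):
        with pytest.raises(ValueError):
            Segment("step", 10.0, -80.0, -70.0)
        with pytest.raises(ValueError):
            Segment("step", 0.0, -80.0, -80.0)
        with pytest.raises(ValueError):
            Segment("sine", 10.0, -80.0, -80.0)


class TestWindowExtraction:
    def test_constant_trace(self, timepoints):
        t = np.arange(0.0, 10_000.5, 0.5)
        tr = make_trace(t, np.full_like(t, 3.25), "A/F")
        feats = extract_vc_features(tr, timepoints)
        assert all(v == pytest.approx(3.25) for v in feats.values())

    def test_identity_ramp(self, timepoints):
        t = np.arange(0.0, 10_000.01, 0.1)
        tr = make_trace(t, t.copy(), "A/F")
        feats = extract_vc_features(tr, timepoints)
        for tp in timepoints:
            if tp.method == "avg":
                assert feats[tp.label] == pytest.approx(tp.t_center)
            else:
                assert feats[tp.label] == pytest.approx(tp.t_center - 1.0)

    def test_min_captures_spike(self, timepoints):
        t = np.arange(0.0, 10_000.5, 0.5)
        v = np.zeros_like(t)
        v[np.argmin(np.abs(t - 1986.5))] = -40.0
        feats = extract_vc_features(make_trace(t, v, "A/F"), timepoints)
        assert feats["I_CaL"] == -40.0

    def test_empty_window_names_spec(self):
        tr = make_trace([0.0, 1.0], [0.0, 0.0], "A/F")
        with pytest.raises(ValueError, match="I_Ks"):
            extract_vc_features(tr, [TimePointSpec("I_Ks", 9040.0, "avg")])

    def test_matches_bruteforce_on_random_traces(self, timepoints):
        """Window extraction equals a brute-force scan over raw samples."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            dt = rng.choice([0.1, 0.25, 0.5])
            t = np.arange(0.0, 10_000.0 + dt, dt)
            v = rng.normal(0.0, 5.0, t.size)
            tr = make_trace(t, v, "A/F")
            feats = extract_vc_features(tr, timepoints)
            for tp in timepoints:
                mask = (t >= tp.t_center - 1.0) & (t <= tp.t_center + 1.0)
                ref = v[mask].min() if tp.method == "min" else v[mask].mean()
                assert feats[tp.label] == pytest.approx(ref, abs=1e-12)

    def test_min_never_exceeds_avg(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 4000.0, 0.5)
        v = rng.normal(0.0, 2.0, t.size)
        tr = make_trace(t, v, "A/F")
        for tc in [600.0, 1262.0, 1986.0]:
            lo = extract_vc_features(tr, [TimePointSpec("x", tc, "min")])["x"]
            hi = extract_vc_features(tr, [TimePointSpec("x", tc, "avg")])["x"]
            assert lo <= hi


def triangle_train(upstrokes, v_rest=-60.0, v_peak=40.0, fall_ms=200.0,
                   dt=0.5, total=10_000.0):
    """Instant rise to v_peak then linear fall back to v_rest."""
    t = np.arange(0.0, total + dt, dt)
    v = np.full_like(t, v_rest)
    rate = (v_peak - v_rest) / fall_ms
    for t0 in upstrokes:
        mask = (t >= t0) & (t <= t0 + fall_ms)
        v[mask] = v_peak - rate * (t[mask] - t0)
    return make_trace(t, v, "mV")


class TestAPDetection:
    def test_flat_trace_is_quiescent(self):
        t = np.arange(0.0, 10_000.0, 1.0)
        tr = make_trace(t, np.full_like(t, -52.0), "mV")
        assert detect_aps(tr) == []
        ap = ap_features(tr)
        assert not ap.spontaneous and ap.MP == -52.0 and ap.n_aps == 0

    def test_counts_synthetic_train(self):
        ups = [1000.0, 2500.0, 4000.0, 5500.0, 7000.0]
        ev = detect_aps(triangle_train(ups), smooth_ms=0)
        assert len(ev) == 5
        np.testing.assert_allclose([e.t_upstroke for e in ev], ups, atol=2.0)

    def test_small_amplitude_ignored(self):
        tr = triangle_train([2000.0], v_rest=-60.0, v_peak=-40.0)
        assert detect_aps(tr, smooth_ms=0) == []

    def test_rejects_current_trace(self):
        t = np.arange(0.0, 2000.0, 1.0)
        with pytest.raises(ValueError):
            detect_aps(make_trace(t, np.zeros_like(t), "A/F"))

    def test_baseline_kernik_is_spontaneous(self, kernik, baseline_artifact):
        from ricp.engine import simulate_cc
        tr = simulate_cc(kernik, baseline_artifact, duration=10_000.0,
                         rtol=1e-6)
        assert len(detect_aps(tr)) >= 1


class TestAPFeatures:
    def test_quiescent_features_absent(self):
        t = np.arange(0.0, 10_000.0, 1.0)
        ap = ap_features(make_trace(t, np.full_like(t, -27.0), "mV"))
        assert ap.MP == -27.0
        assert ap.APD90 is None and ap.CL is None and ap.dVdt_max is None

    def test_triangle_apd90_closed_form(self):
        """100 mV fall over 200 ms: 90 mV of repolarisation at
        0.5 mV/ms takes 180 ms."""
        ap = ap_features(triangle_train([2000.0, 5000.0]), smooth_ms=0)
        assert ap.spontaneous and ap.n_aps == 2
        assert ap.APD90 == pytest.approx(180.0, abs=2.0)
        assert ap.MP == pytest.approx(-60.0, abs=0.5)

    def test_cycle_length_between_upstrokes(self):
        ap = ap_features(triangle_train([1000.0, 2400.0]), smooth_ms=0)
        assert ap.CL == pytest.approx(1400.0, abs=2.0)

    def test_time_shift_invariance(self):
        tr = triangle_train([1500.0, 3100.0, 4700.0])
        ap1 = ap_features(tr, smooth_ms=0)
        ap2 = ap_features(tr.shifted(250.0), smooth_ms=0)
        assert ap1.MP == ap2.MP
        assert ap1.APD90 == pytest.approx(ap2.APD90, abs=1e-9)
        assert ap1.CL == pytest.approx(ap2.CL, abs=1e-9)

    def test_cov_requires_three_cycles(self):
        two = ap_features(triangle_train([1000.0, 2400.0]), smooth_ms=0)
        assert two.CoV_CL is None
        four = ap_features(triangle_train([1000.0, 2400.0, 3800.0, 5200.0]),
                           smooth_ms=0)
        assert four.CoV_CL == pytest.approx(0.0, abs=1e-9)

    @given(st.floats(min_value=-500.0, max_value=500.0))
    @settings(max_examples=20, deadline=None)
    def test_shift_invariance_property(self, dt):
        tr = triangle_train([1200.0, 2600.0])
        a = ap_features(tr, smooth_ms=0)
        b = ap_features(tr.shifted(dt), smooth_ms=0)
        assert a.n_aps == b.n_aps
        assert a.MP == pytest.approx(b.MP, abs=1e-9)
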