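import numpy as np
import pytest

from mirrorvitals.errors import ConfigurationError, StreamError
from mirrorvitals.signal_core import FaceObservation, RGBTrace
from mirrorvitals.streaming_session import (
    AffectSample,
    SessionConfig,
    StreamingSession,
    infer_fs,
    run_batch,
)
from mirrorvitals.synthetic_scene import SceneConfig, generate_rgb_trace
from mirrorvitals.vitals import VitalsEstimate


def push_trace(session, trace, faces=None):
    """Push every trace sample; returns emitted estimates."""
    out = []
    for i, (t, v) in enumerate(zip(trace.times, trace.values)):
        face = faces[i] if faces is not None else FaceObservation(box=(0, 0, 1, 1))
        est = session.push_frame(t, tuple(v), face)
        if est is not None:
            out.append(est)
    return out


class TestPushFrame:
    def test_no_estimate_during_stabilization(self, full_face):
        cfg = SceneConfig(fs=30, duration_s=26, hr_hz=1.3)
        trace, _ = generate_rgb_trace(cfg)
        session = StreamingSession()
        assert push_trace(session, trace) == []

    def test_30s_stream_emits_accurate_estimates(self):
        cfg = SceneConfig(fs=30, duration_s=30, hr_hz=1.3)
        trace, _ = generate_rgb_trace(cfg)
        session = StreamingSession()
        out = push_trace(session, trace)
        assert len(out) >= 3
        for est in out:
            assert est.hr_bpm == pytest.approx(78.0, abs=1.0)

    def test_low_confidence_sample_masked(self):
        session = StreamingSession()
        session.push_frame(0.0, (1, 1, 1), FaceObservation(box=(0, 0, 1, 1), confidence=0.65))
        assert session._valid == [False]
        session.push_frame(1 / 30, (1, 1, 1), FaceObservation(box=(0, 0, 1, 1), confidence=0.9))
        assert session._valid == [False, True]

    def test_non_monotone_timestamp_raises(self, full_face):
        session = StreamingSession()
        session.push_frame(0.0, (1, 1, 1), full_face)
        with pytest.raises(StreamError):
            session.push_frame(0.0, (1, 1, 1), full_face)

    def test_jitter_beyond_tolerance_raises(self, full_face):
        session = StreamingSession()
        t = 0.0
        for _ in range(40):
            session.push_frame(t, (1, 1, 1), full_face)
            t += 1 / 30
        with pytest.raises(StreamError):
            session.push_frame(t + 0.5, (1, 1, 1), full_face)  # a dropped half-second

    def test_phase_transition(self, clean_trace):
        session = StreamingSession()
        assert session.phase == "stabilizing"
        push_trace(session, clean_trace)
        assert session.phase == "estimating"
        session.stop()
        assert session.phase == "stopped"
        with pytest.raises(StreamError):
            session.push_frame(100.0, (1, 1, 1), FaceObservation(box=(0, 0, 1, 1)))


class TestStreamingBatchEquivalence:
    def test_identical_estimates(self, clean_trace):
        session = StreamingSession()
        streamed = push_trace(session, clean_trace)
        batched = run_batch(clean_trace)
        assert len(streamed) == len(batched) > 0
        for a, b in zip(streamed, batched):
            assert abs(a.hr_bpm - b.hr_bpm) <= 1e-9
            assert abs(a.spo2_pct - b.spo2_pct) <= 1e-9
            assert abs(a.snr - b.snr) <= 1e-9
            assert a.window == b.window
            assert a.valid == b.valid

    def test_noisy_trace_equivalence(self):
        cfg = SceneConfig(fs=30, duration_s=40, noise_sd=0.4, seed=21)
        trace, _ = generate_rgb_trace(cfg)
        streamed = push_trace(StreamingSession(), trace)
        batched = run_batch(trace)
        for a, b in zip(streamed, batched):
            assert abs(a.hr_bpm - b.hr_bpm) <= 1e-9

    def test_short_trace_warns_and_returns_empty(self):
        cfg = SceneConfig(fs=30, duration_s=10)
        trace, _ = generate_rgb_trace(cfg)
        with pytest.warns(UserWarning, match="stabilization"):
            assert run_batch(trace) == []

    def test_invalid_gap_excluded_from_valid_seconds(self, clean_trace):
        # mark 5 s in the middle of the estimating phase invalid
        trace = RGBTrace(
            fs=clean_trace.fs, values=clean_trace.values.copy(),
            valid=clean_trace.valid.copy(), confidence=clean_trace.confidence.copy(),
        )
        gap = slice(int(30 * trace.fs), int(35 * trace.fs))
        trace.valid[gap] = False
        trace.confidence[gap] = 0.4
        batched = run_batch(trace)
        gap_windows = [e for e in batched if not e.valid and "invalid_samples" in e.reasons]
        assert gap_windows, "windows overlapping the gap must be invalid"
        post = [e for e in batched if e.window[0] >= 35.1 + 1e-6]
        assert post and all(e.valid for e in post), "estimates resume after the gap"

    def test_no_estimate_before_stabilization_invariant(self, clean_trace):
        for est in run_batch(clean_trace):
            assert est.window[1] >= 26.0 - 2.6  # window end is delay-compensated


class TestValidSeconds:
    def test_accrues_one_stride_per_valid_window(self, clean_trace):
        session = StreamingSession()
        out = push_trace(session, clean_trace)
        n_valid = sum(1 for e in out if e.valid and e.snr > session.config.snr_gate)
        assert session.valid_seconds == pytest.approx(n_valid * session.config.stride_s)

    def test_bounded_by_elapsed_minus_stabilization(self, clean_trace):
        session = StreamingSession()
        for t, v in zip(clean_trace.times, clean_trace.values):
            session.push_frame(t, tuple(v), FaceObservation(box=(0, 0, 1, 1)))
            bound = max(0.0, session.elapsed_s - session.config.stabilization_s) + 1e-9
            assert session.valid_seconds <= bound

    def test_low_snr_windows_do_not_accrue(self):
        session = StreamingSession()
        est = VitalsEstimate(hr_bpm=70, f_h=70 / 60, snr=0.65, valid=True)
        for _ in range(20):
            session._record(est)
        assert session.valid_seconds == 0.0


class TestTrigger:
    def ready_session(self, valid_seconds=9.0, conf=0.85, affect=("happy", 0.8)):
        session = StreamingSession()
        session.phase = "estimating"
        session.valid_seconds = valid_seconds
        session._t = [0.0]
        est = VitalsEstimate(hr_bpm=78, snr=1.0, valid=True, face_confidence=conf)
        session.estimates.append(est)
        if affect:
            session.push_affect(AffectSample(0.0, affect[0], affect[1], "20s", 0.9))
        return session

    def test_fires_when_all_conditions_met(self):
        session = self.ready_session()
        fired, reasons = session.gate_chatbot_trigger()
        assert fired and reasons == []
        assert session.phase == "triggered"

    def test_insufficient_valid_seconds(self):
        session = self.ready_session(valid_seconds=7.5)
        fired, reasons = session.gate_chatbot_trigger()
        assert not fired
        assert "insufficient_valid_seconds" in reasons

    def test_low_face_confidence(self):
        session = self.ready_session(conf=0.65)
        fired, reasons = session.gate_chatbot_trigger()
        assert not fired and "low_face_confidence" in reasons

    def test_no_affect_label(self):
        session = self.ready_session(affect=None)
        fired, reasons = session.gate_chatbot_trigger()
        assert not fired and "no_affect_label" in reasons

    def test_affect_below_half_confidence_insufficient(self):
        session = self.ready_session(affect=("neutral", 0.45))
        fired, reasons = session.gate_chatbot_trigger()
        assert not fired and "no_affect_label" in reasons

    def test_monotone_under_frozen_quality(self):
        session = self.ready_session()
        assert session.gate_chatbot_trigger()[0]
        # further valid windows only ever add valid seconds
        for _ in range(5):
            session._record(VitalsEstimate(hr_bpm=78, snr=1.0, valid=True, face_confidence=0.9))
            assert session.gate_chatbot_trigger()[0]

    def test_trigger_log_records_decisions(self):
        session = self.ready_session(valid_seconds=2.0)
        session.gate_chatbot_trigger()
        assert session.trigger_log[-1]["fired"] is False
        assert "insufficient_valid_seconds" in session.trigger_log[-1]["reasons"]


class TestAffectVotes:
    def test_age_vote_pending_below_quorum(self):
        session = StreamingSession()
        for i in range(29):
            session.push_affect(AffectSample(i * 1.0, "happy", 0.9, "20s", 0.8))
        assert session.age_vote() is None

    def test_age_vote_majority(self):
        session = StreamingSession()
        for i in range(17):
            session.push_affect(AffectSample(i, "happy", 0.9, "20s", 0.8))
        for i in range(13):
            session.push_affect(AffectSample(17 + i, "happy", 0.9, "30s", 0.8))
        label, count, frac = session.age_vote()
        assert (label, count) == ("20s", 17)
        assert frac == pytest.approx(17 / 30)

    def test_bad_affect_confidence_rejected(self):
        session = StreamingSession()
        with pytest.raises(ConfigurationError):
            session.push_affect(AffectSample(0.0, "happy", 1.5, "20s", 0.8))


class TestConfigAndFs:
    def test_invalid_session_configs(self):
        with pytest.raises(ConfigurationError):
            SessionConfig(stride_s=3.0, window_s=2.0)
        with pytest.raises(ConfigurationError):
            SessionConfig(stabilization_s=1.0)
        with pytest.raises(ConfigurationError):
            SessionConfig(min_valid_s=0)
        with pytest.raises(ConfigurationError):
            SessionConfig(face_conf_gate=1.5)

    def test_infer_fs_uniform(self):
        assert infer_fs(np.arange(100) / 30.0) == pytest.approx(30.0)

    def test_infer_fs_jitter_error(self):
        t = np.arange(50) / 30.0
        t[20] += 0.01
        with pytest.raises(StreamError):
            infer_fs(t)

    def test_analysis_window_covers_two_cycles_at_band_floor(self):
        cfg = SessionConfig()
        assert cfg.analysis_samples(30.0) == 100  # ceil(2 * 30 / 0.6)
        narrow = SessionConfig(hr_band=(0.7, 3.5))
        assert narrow.analysis_samples(30.0) == int(np.ceil(2 * 30 / 0.7))
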