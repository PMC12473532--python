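"""Real-time engine: rolling windows over a frame-sample stream with
stabilization, per-window validity gating, and the chatbot trigger.

Scheduling model
----------------
No estimate is emitted during the stabilization phase (default 26 s).
After that, an estimate is emitted at every stride boundary
``t0 + stabilization_s + k * stride_s`` (k = 1, 2, ...).  At each boundary
the accumulated chrominance series is causally bandpass filtered with
group-delay compensation, and the most recent analysis window of the
compensated pulse yields HR, SNR, and SpO2.

The analysis window is ``max(window_s, 2 / band_low)`` seconds so the
spectral estimator always sees at least two cardiac cycles at the band
floor; ``window_s`` (default 2 s) remains the stride-level reporting
cadence.

A window accrues toward ``valid_seconds`` (one stride quantum per window)
iff its estimate is valid and its SNR exceeds ``snr_gate``.  The chatbot
trigger fires once ``valid_seconds >= min_valid_s``, the latest window's
mean face confidence exceeds ``face_conf_gate``, and at least one affect
label with confidence > 0.5 has been observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import ConfigurationError, StreamError
from .signal_core import (
    DEFAULT_BAND,
    BandpassSpec,
    FaceObservation,
    RGBTrace,
    apply_bandpass,
    design_bandpass,
)
from .vitals import (
    SpO2Calibration,
    VitalsEstimate,
    compute_snr,
    estimate_spo2,
    spo2_components,
)
from . import signal_core, vitals

_EPS = 1e-9

#: Relative frame-interval jitter tolerated when inferring the sampling rate.
FS_JITTER_TOL = 0.05


def infer_fs(times: np.ndarray, jitter_tol: float = FS_JITTER_TOL) -> float:
    """Sampling rate from frame timestamps: 1 / median interval.

    The result is rounded to 1e-6 Hz so the streaming and batch paths
    agree bit-exactly regardless of how many intervals the median saw.
    Raises :class:`StreamError` when any interval deviates from the
    median by more than ``jitter_tol``.
    """
    dts = np.diff(np.asarray(times, dtype=float))
    if len(dts) == 0:
        raise StreamError("need at least two timestamps to infer fs")
    med = float(np.median(dts))
    if med <= 0:
        raise StreamError("cannot infer sampling rate from timestamps")
    if np.any(np.abs(dts - med) > jitter_tol * med):
        raise StreamError(
            f"frame-interval jitter exceeds {jitter_tol:.0%} of median {med:.4f}s"
        )
    return round(1.0 / med, 6)


@dataclass(frozen=True)
class SessionConfig:
    window_s: float = 2.0
    stride_s: float = 1.0
    stabilization_s: float = 26.0
    min_valid_s: float = 8.0
    snr_gate: float = 0.7
    face_conf_gate: float = 0.70
    hr_band: Tuple[float, float] = DEFAULT_BAND
    affect_votes: int = 30
    fir_order: Optional[int] = None
    spo2_cal: SpO2Calibration = SpO2Calibration()

    def __post_init__(self):
        if not (0 < self.stride_s <= self.window_s):
            raise ConfigurationError(
                f"stride must satisfy 0 < stride <= window, got {self.stride_s}/{self.window_s}"
            )
        if self.stabilization_s < self.window_s:
            raise ConfigurationError("stabilization must be at least one window long")
        if self.min_valid_s <= 0:
            raise ConfigurationError("min_valid_s must be positive")
        if not (0 <= self.face_conf_gate <= 1):
            raise ConfigurationError("face_conf_gate must lie in [0, 1]")
        if self.snr_gate < 0:
            raise ConfigurationError("snr_gate must be >= 0")

    def bandpass_spec(self) -> BandpassSpec:
        return BandpassSpec(low_hz=self.hr_band[0], high_hz=self.hr_band[1], order=self.fir_order)

    def analysis_samples(self, fs: float) -> int:
        by_window = int(round(self.window_s * fs))
        by_band = int(np.ceil(2.0 * fs / self.hr_band[0]))
        return max(by_window, by_band)


@dataclass
class AffectSample:
    t: float
    emotion: str
    emotion_conf: float
    age_bucket: str
    age_conf: float


def _window_estimate(
    values: np.ndarray,
    valid_mask: np.ndarray,
    confidence: np.ndarray,
    n_end: int,
    fs: float,
    t0: float,
    config: SessionConfig,
    taps: np.ndarray,
) -> Optional[VitalsEstimate]:
    """Estimate over the latest analysis window of the first ``n_end`` samples.

    Shared by the streaming and batch paths so the two are bit-identical
    on identical input.  Returns None when the compensated series is still
    too short.
    """
    delay = (len(taps) - 1) // 2
    win = config.analysis_samples(fs)
    aligned = n_end - delay
    if aligned < win:
        return None
    r = values[:n_end, 0]
    g = values[:n_end, 1]
    b = values[:n_end, 2]
    xs = 3.0 * r - 2.0 * g
    ys = 1.5 * r + g - 1.5 * b
    # per-prefix mean removal keeps the causal filter transient small
    xf = apply_bandpass(xs - xs.mean(), taps, mode="stream")
    yf = apply_bandpass(ys - ys.mean(), taps, mode="stream")
    lo, hi = aligned - win, aligned
    span = (t0 + lo / fs, t0 + hi / fs)
    pulse = signal_core.pulse_signal(xf[lo:hi], yf[lo:hi], window=span, xs=xs[lo:hi], ys=ys[lo:hi])
    est = vitals.estimate_hr(pulse, fs, band=config.hr_band)
    est.window = span
    est.face_confidence = float(np.mean(confidence[lo:hi]))
    if not bool(np.all(valid_mask[lo:hi])):
        est.invalidate("invalid_samples")
    if est.f_h is not None:
        est.snr = compute_snr(pulse, fs, est.f_h, band=config.hr_band)
    comps = spo2_components(RGBTrace(fs=fs, values=values[lo:hi]))
    spo2, clamped, reason = estimate_spo2(comps, config.spo2_cal)
    if reason is not None:
        est.invalidate(reason)
    est.spo2_pct = spo2
    est.spo2_clamped = clamped
    return est


class StreamingSession:
    """Push-driven session over (timestamp, V_R, V_G, V_B, FaceObservation)."""

    FS_PROBE_FRAMES = 30
    FS_JITTER_TOL = 0.05

    def __init__(self, config: SessionConfig = SessionConfig()):
        self.config = config
        self.phase = "stabilizing"
        self.valid_seconds = 0.0
        self.estimates: List[VitalsEstimate] = []
        self.trigger_log: List[dict] = []
        self.affect_samples: List[AffectSample] = []
        self.fs: Optional[float] = None
        self._taps: Optional[np.ndarray] = None
        self._t: List[float] = []
        self._values: List[Tuple[float, float, float]] = []
        self._valid: List[bool] = []
        self._conf: List[float] = []

    # -- state -------------------------------------------------------------
    @property
    def elapsed_s(self) -> float:
        return self._t[-1] - self._t[0] if len(self._t) > 1 else 0.0

    def _infer_fs(self) -> None:
        self.fs = infer_fs(self._t, jitter_tol=self.FS_JITTER_TOL)
        self._taps = design_bandpass(self.fs, self.config.bandpass_spec())

    # -- ingestion ---------------------------------------------------------
    def push_frame(
        self,
        timestamp: float,
        rgb: Tuple[float, float, float],
        face: Optional[FaceObservation],
    ) -> Optional[VitalsEstimate]:
        """Append one frame sample; returns an estimate at stride boundaries."""
        if self.phase == "stopped":
            raise StreamError("session already stopped")
        if self._t and timestamp <= self._t[-1]:
            raise StreamError(
                f"timestamps must be strictly increasing ({timestamp} after {self._t[-1]})"
            )
        if self.fs is not None:
            dt = timestamp - self._t[-1]
            if abs(dt - 1.0 / self.fs) > self.FS_JITTER_TOL / self.fs:
                raise StreamError(
                    f"frame interval {dt:.4f}s deviates more than "
                    f"{self.FS_JITTER_TOL:.0%} from 1/fs={1.0 / self.fs:.4f}s"
                )
        conf = face.confidence if face is not None else 0.0
        valid = face is not None and conf >= self.config.face_conf_gate
        self._t.append(float(timestamp))
        self._values.append(tuple(float(v) for v in rgb))
        self._valid.append(valid)
        self._conf.append(float(conf))
        if self.fs is None:
            if len(self._t) < self.FS_PROBE_FRAMES:
                return None
            self._infer_fs()
        elapsed = self._t[-1] - self._t[0]
        if self.phase == "stabilizing" and elapsed + _EPS >= self.config.stabilization_s:
            self.phase = "estimating"
        next_emit = self.config.stabilization_s + (len(self.estimates) + 1) * self.config.stride_s
        if elapsed + _EPS < next_emit:
            return None
        est = _window_estimate(
            np.asarray(self._values),
            np.asarray(self._valid),
            np.asarray(self._conf),
            len(self._values),
            self.fs,
            self._t[0],
            self.config,
            self._taps,
        )
        if est is None:
            return None
        self._record(est)
        return est

    def push_affect(self, sample: AffectSample) -> None:
        if not (0 <= sample.emotion_conf <= 1 and 0 <= sample.age_conf <= 1):
            raise ConfigurationError("affect confidences must lie in [0, 1]")
        self.affect_samples.append(sample)

    def _record(self, est: VitalsEstimate) -> None:
        self.estimates.append(est)
        if est.valid and est.snr > self.config.snr_gate:
            self.valid_seconds += self.config.stride_s

    # -- trigger -----------------------------------------------------------
    def gate_chatbot_trigger(self) -> Tuple[bool, List[str]]:
        """Decide whether enough trustworthy signal exists to talk."""
        reasons: List[str] = []
        if self.phase == "stabilizing":
            reasons.append("stabilizing")
        if self.valid_seconds < self.config.min_valid_s:
            reasons.append("insufficient_valid_seconds")
        latest = self.estimates[-1] if self.estimates else None
        if latest is None or latest.face_confidence is None or (
            latest.face_confidence <= self.config.face_conf_gate
        ):
            reasons.append("low_face_confidence")
        if not any(s.emotion_conf > 0.5 for s in self.affect_samples):
            reasons.append("no_affect_label")
        fired = not reasons
        self.trigger_log.append(
            {
                "t": self._t[-1] if self._t else None,
                "fired": fired,
                "reasons": list(reasons),
                "valid_seconds": self.valid_seconds,
            }
        )
        if fired and self.phase == "estimating":
            self.phase = "triggered"
        return fired, reasons

    def age_vote(self) -> Optional[Tuple[str, int, float]]:
        """Majority vote over the last ``affect_votes`` age labels, or None."""
        from .affect_geometry import majority_vote

        labels = [s.age_bucket for s in self.affect_samples]
        return majority_vote(labels, n_required=self.config.affect_votes)

    def stop(self) -> None:
        self.phase = "stopped"


def run_batch(trace: RGBTrace, config: SessionConfig = SessionConfig()) -> List[VitalsEstimate]:
    """Offline twin of the streaming loop over a fully materialized trace.

    Emits the same estimate sequence as pushing the trace frame-by-frame
    through :class:`StreamingSession` (identical window math and schedule).
    """
    duration = (len(trace) - 1) / trace.fs
    if duration + _EPS < config.stabilization_s + config.stride_s:
        warnings.warn(
            f"trace of {duration:.1f}s shorter than stabilization+stride "
            f"({config.stabilization_s + config.stride_s:.1f}s); no estimates",
            stacklevel=2,
        )
        return []
    times = trace.times
    fs = infer_fs(times)  # same inference as the streaming path: bit-identical results
    taps = design_bandpass(fs, config.bandpass_spec())
    estimates: List[VitalsEstimate] = []
    for i in range(len(trace)):
        elapsed = times[i] - times[0]
        next_emit = config.stabilization_s + (len(estimates) + 1) * config.stride_s
        if elapsed + _EPS < next_emit:
            continue
        est = _window_estimate(
            trace.values, trace.valid, trace.confidence, i + 1,
            fs, trace.t0, config, taps,
        )
        if est is not None:
            estimates.append(est)
    return estimates
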