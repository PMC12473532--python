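"""Trace-to-pulse chain: ROI averaging, chrominance transform, FIR bandpass,
and skin-tone-normalized pulse extraction.

The chain converts a stream of facial-ROI frames into a blood-volume pulse:

1. each frame's ROI is spatially averaged per channel into ``(V_R, V_G, V_B)``;
2. the RGB trace is projected onto two chrominance axes
   ``Xs = 3 V_R - 2 V_G`` and ``Ys = 1.5 V_R + V_G - 1.5 V_B``;
3. both chrominance series are bandpass filtered to the cardiac band
   (default 0.6-4.0 Hz, windowed-sinc FIR);
4. the pulse is ``S = Xf - alpha * Yf`` with ``alpha = sigma(Xf)/sigma(Yf)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, EmptyInputError, SignalQualityError

#: Default cardiac passband (Hz).
DEFAULT_BAND = (0.6, 4.0)
#: Narrower preset used by the real-time deployment configuration.
NARROW_BAND_PRESET = (0.7, 3.5)


@dataclass(frozen=True)
class FaceObservation:
    """A detected face box with confidence and optional landmarks.

    The box is ``(x, y, w, h)`` in pixels, 0-based, origin at the top-left,
    half-open extent: pixel columns ``x .. x+w-1`` and rows ``y .. y+h-1``.
    """

    box: Tuple[float, float, float, float]
    confidence: float = 1.0
    landmarks: Optional[dict] = None

    def __post_init__(self):
        x, y, w, h = self.box
        if w <= 0 or h <= 0:
            raise ConfigurationError(f"face box must have positive extent, got w={w}, h={h}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ConfigurationError(f"confidence must lie in [0, 1], got {self.confidence}")


@dataclass
class RGBTrace:
    """Spatially averaged per-frame channel means: the 3xN temporal signal.

    ``values`` is an (N, 3) float array of (V_R, V_G, V_B) per frame.
    ``valid`` marks frames whose ROI average succeeded and whose face
    confidence passed upstream gating; ``confidence`` carries the raw
    per-frame detector confidence when known.
    """

    fs: float
    values: np.ndarray
    t0: float = 0.0
    valid: np.ndarray = None
    confidence: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ConfigurationError(f"trace values must be (N, 3), got {self.values.shape}")
        if len(self.values) < 1:
            raise EmptyInputError("trace must contain at least one sample")
        if not self.fs > 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("trace contains non-finite values")
        if self.valid is None:
            self.valid = np.ones(len(self.values), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.confidence is None:
            self.confidence = np.ones(len(self.values), dtype=float)
        else:
            self.confidence = np.asarray(self.confidence, dtype=float)
        if len(self.valid) != len(self.values) or len(self.confidence) != len(self.values):
            raise ConfigurationError("validity/confidence masks must match trace length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    @property
    def red(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def green(self) -> np.ndarray:
        return self.values[:, 1]

    @property
    def blue(self) -> np.ndarray:
        return self.values[:, 2]


@dataclass(frozen=True)
class BandpassSpec:
    """Linear-phase FIR bandpass specification.

    ``order`` is the tap count minus one and must be even so the group
    delay (order/2 samples) is an integer. ``order=None`` selects the
    default rule: next even integer >= 3 * fs / low_hz, capped at 10 s
    of taps.
    """

    low_hz: float = DEFAULT_BAND[0]
    high_hz: float = DEFAULT_BAND[1]
    order: Optional[int] = None
    design: str = "hamming"

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise ConfigurationError(
                f"band edges must satisfy 0 < low < high, got ({self.low_hz}, {self.high_hz})"
            )
        if self.order is not None and (self.order < 2 or self.order % 2):
            raise ConfigurationError(f"FIR order must be even and >= 2, got {self.order}")

    def resolved_order(self, fs: float) -> int:
        if self.order is not None:
            return self.order
        order = int(np.ceil(3.0 * fs / self.low_hz))
        order = min(order, int(10.0 * fs))
        return order + (order % 2)


@dataclass
class ChrominancePulse:
    """Chrominance pair, filtered pair, normalization factor, and pulse."""

    xs: np.ndarray
    ys: np.ndarray
    xf: np.ndarray
    yf: np.ndarray
    alpha: float
    s: np.ndarray
    window: Tuple[float, float] = (0.0, 0.0)


def spatial_average_frame(frame: np.ndarray, roi: FaceObservation) -> Tuple[float, float, float]:
    """Mean of each colour channel over the ROI clipped to the frame.

    Raises :class:`SignalQualityError` when the clipped ROI is empty; the
    caller marks the frame invalid rather than aborting the stream.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ConfigurationError(f"frame must be HxWx3, got shape {frame.shape}")
    h_frame, w_frame = frame.shape[:2]
    x, y, w, h = roi.box
    x0 = max(int(np.floor(x)), 0)
    y0 = max(int(np.floor(y)), 0)
    x1 = min(int(np.floor(x + w)), w_frame)
    y1 = min(int(np.floor(y + h)), h_frame)
    if x1 <= x0 or y1 <= y0:
        raise SignalQualityError("ROI does not intersect the frame")
    patch = frame[y0:y1, x0:x1, :]
    means = patch.reshape(-1, 3).mean(axis=0)
    return float(means[0]), float(means[1]), float(means[2])


def build_rgb_trace(
    frames: Sequence[np.ndarray],
    rois: Sequence[Optional[FaceObservation]],
    fs: float,
) -> RGBTrace:
    """Assemble an :class:`RGBTrace` from frames and per-frame ROIs.

    Frames without a usable ROI are marked invalid in the trace mask; their
    sample holds the previous valid value (or the first valid value for a
    leading gap) so downstream filtering stays numerically stable.
    """
    if fs <= 0:
        raise ConfigurationError(f"fs must be positive, got {fs}")
    n = len(frames)
    if n != len(rois):
        raise ConfigurationError("one ROI (or None) required per frame")
    values = np.zeros((n, 3))
    valid = np.zeros(n, dtype=bool)
    conf = np.zeros(n)
    for i, (frame, roi) in enumerate(zip(frames, rois)):
        if roi is None:
            continue
        try:
            values[i] = spatial_average_frame(frame, roi)
        except SignalQualityError:
            continue
        valid[i] = True
        conf[i] = roi.confidence
    if not valid.any():
        raise EmptyInputError("no frame produced a valid ROI average")
    # fill invalid slots by hold-last (backfill the leading gap)
    last = values[np.argmax(valid)]
    for i in range(n):
        if valid[i]:
            last = values[i]
        else:
            values[i] = last
    first_valid = int(np.argmax(valid))
    values[:first_valid] = values[first_valid]
    return RGBTrace(fs=fs, values=values, valid=valid, confidence=conf)


def chrominance_transform(trace: RGBTrace) -> Tuple[np.ndarray, np.ndarray]:
    """Project RGB means onto the two chrominance axes.

    ``xs = 3 V_R - 2 V_G``; ``ys = 1.5 V_R + V_G - 1.5 V_B``.
    """
    r, g, b = trace.red, trace.green, trace.blue
    xs = 3.0 * r - 2.0 * g
    ys = 1.5 * r + g - 1.5 * b
    return xs, ys


def design_bandpass(fs: float, spec: BandpassSpec = BandpassSpec()) -> np.ndarray:
    """Windowed-sinc linear-phase FIR bandpass coefficients."""
    if not spec.high_hz < fs / 2:
        raise ConfigurationError(
            f"high band edge {spec.high_hz} Hz infeasible at fs={fs} (needs < fs/2)"
        )
    order = spec.resolved_order(fs)
    taps = sps.firwin(
        order + 1,
        [spec.low_hz, spec.high_hz],
        window=spec.design,
        pass_zero=False,
        fs=fs,
    )
    return taps


def apply_bandpass(series: np.ndarray, coefficients: np.ndarray, mode: str = "batch") -> np.ndarray:
    """Filter a series with an FIR bandpass.

    ``batch`` applies the filter forward-backward (zero phase).  ``stream``
    applies it causally and compensates the integer group delay
    (``order/2`` samples) by shifting the output left; the final
    ``order/2`` samples hold the last computed value and are transient.
    Output length equals input length in both modes.
    """
    series = np.asarray(series, dtype=float)
    taps = np.asarray(coefficients, dtype=float)
    if mode == "batch":
        if len(series) <= len(taps):
            raise SignalQualityError(
                f"series of {len(series)} samples too short for batch filtering "
                f"({len(taps)} taps)"
            )
        padlen = min(3 * len(taps), len(series) - 1)
        return sps.filtfilt(taps, [1.0], series, padlen=padlen)
    if mode == "stream":
        delay = (len(taps) - 1) // 2
        y = sps.lfilter(taps, [1.0], series)
        out = np.empty_like(y)
        out[: len(y) - delay] = y[delay:]
        out[len(y) - delay:] = y[-1] if len(y) else 0.0
        return out
    raise ConfigurationError(f"unknown filter mode {mode!r}")


def extract_pulse(
    trace: RGBTrace, spec: BandpassSpec = BandpassSpec(), mode: str = "batch"
) -> ChrominancePulse:
    """Full chain on a trace: detrend, chrominance, bandpass, pulse.

    In ``stream`` mode the delay-compensated tail transient (order/2
    samples) is dropped, so the returned pulse is shorter than the trace.
    """
    taps = design_bandpass(trace.fs, spec)
    xs, ys = chrominance_transform(trace)
    xf = apply_bandpass(xs - xs.mean(), taps, mode=mode)
    yf = apply_bandpass(ys - ys.mean(), taps, mode=mode)
    if mode == "stream":
        delay = (len(taps) - 1) // 2
        if len(xf) <= delay:
            raise SignalQualityError("trace shorter than the filter group delay")
        xs, ys, xf, yf = xs[:-delay], ys[:-delay], xf[:-delay], yf[:-delay]
    window = (trace.t0, trace.t0 + len(xf) / trace.fs)
    return pulse_signal(xf, yf, window=window, xs=xs, ys=ys)


def pulse_signal(
    xf: np.ndarray, yf: np.ndarray, window: Tuple[float, float] = (0.0, 0.0),
    xs: Optional[np.ndarray] = None, ys: Optional[np.ndarray] = None,
) -> ChrominancePulse:
    """Combine filtered chrominance into the pulse ``S = Xf - alpha Yf``.

    ``alpha`` is the ratio of population standard deviations
    ``sigma(Xf) / sigma(Yf)``; when ``sigma(Yf) == 0`` the degenerate rule
    ``alpha = 0, S = Xf`` applies.
    """
    xf = np.asarray(xf, dtype=float)
    yf = np.asarray(yf, dtype=float)
    if xf.shape != yf.shape:
        raise SignalQualityError("xf and yf must have equal length")
    if len(xf) < 2:
        raise SignalQualityError("pulse extraction needs at least 2 samples")
    sx = float(np.std(xf))  # population (ddof=0) by contract
    sy = float(np.std(yf))
    if sy == 0.0:
        alpha = 0.0
        s = xf.copy()
    else:
        alpha = sx / sy
        s = xf - alpha * yf
    return ChrominancePulse(
        xs=xs if xs is not None else xf.copy(),
        ys=ys if ys is not None else yf.copy(),
        xf=xf, yf=yf, alpha=alpha, s=s, window=window,
    )
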