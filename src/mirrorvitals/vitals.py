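"""Per-window physiological estimates: heart rate, SpO2, and signal quality.

Heart rate is the dominant in-band spectral frequency of the pulse,
``HR = 60 * f_h``.  SpO2 follows the two-wavelength ratio-of-ratios model
``SpO2 = A - B * (AC_R/DC_R)/(AC_B/DC_B)`` with the published calibration
constants A = 125, B = 26, where DC is the window mean and AC the window
population standard deviation of the raw red/blue channels.

The SNR score is a fundamental-plus-harmonic band-power ratio: power near
f_h and 2 f_h (clipped to the analysis band) over the remaining in-band
power.  The published system states only the gate value (0.7), not the
formula; this de Haan-style definition is the documented choice.  The
mask half-width is ``max(0.1, 1/T)`` Hz for a T-second window so the
signal mask always covers the window-limited spectral mainlobe — with a
fixed +/-0.1 Hz mask a clean sinusoid in a 2-3 s window would score
below the gate purely from spectral leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .errors import SignalQualityError
from .signal_core import DEFAULT_BAND, ChrominancePulse, RGBTrace

#: Published ratio-of-ratios calibration.
SPO2_A = 125.0
SPO2_B = 26.0

#: Target spectral bin spacing (Hz) after zero padding.
SPECTRAL_RESOLUTION_HZ = 0.02

#: Minimum half-width (Hz) of the signal mask around f_h and its harmonic;
#: widened to 1/T for short windows (see module docstring).
SNR_MASK_MIN_HALFWIDTH_HZ = 0.1


@dataclass(frozen=True)
class SpO2Calibration:
    A: float = SPO2_A
    B: float = SPO2_B
    clamp: Tuple[float, float] = (0.0, 100.0)

    def __post_init__(self):
        if self.B == 0:
            raise ValueError("calibration slope B must be nonzero")
        if self.clamp[0] > self.clamp[1]:
            raise ValueError("clamp bounds must be ordered")


@dataclass
class SpO2Components:
    """DC (mean) and AC (population sigma) of the raw red and blue channels."""

    dc_red: float
    ac_red: float
    dc_blue: float
    ac_blue: float


@dataclass
class VitalsEstimate:
    """One window's worth of vitals with validity bookkeeping."""

    f_h: Optional[float] = None
    hr_bpm: Optional[float] = None
    spo2_pct: Optional[float] = None
    snr: float = 0.0
    window: Tuple[float, float] = (0.0, 0.0)
    valid: bool = True
    reasons: list = field(default_factory=list)
    spo2_clamped: bool = False
    face_confidence: Optional[float] = None

    def invalidate(self, reason: str) -> "VitalsEstimate":
        self.valid = False
        if reason not in self.reasons:
            self.reasons.append(reason)
        return self


def _padded_spectrum(s: np.ndarray, fs: float) -> Tuple[np.ndarray, np.ndarray]:
    """Hann-tapered, zero-padded magnitude spectrum with <= 0.02 Hz bins."""
    n = len(s)
    tapered = s * np.hanning(n)
    nfft = int(2 ** np.ceil(np.log2(max(n, fs / SPECTRAL_RESOLUTION_HZ))))
    mag = np.abs(np.fft.rfft(tapered, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return freqs, mag


def estimate_hr(
    pulse: ChrominancePulse,
    fs: float,
    band: Tuple[float, float] = DEFAULT_BAND,
) -> VitalsEstimate:
    """Dominant in-band frequency of the pulse, refined by quadratic
    interpolation, reported as ``(f_h, hr_bpm = 60 f_h)``."""
    low, high = band
    s = np.asarray(pulse.s, dtype=float)
    min_len = int(np.ceil(2.0 * fs / low))  # two cardiac cycles at the band floor
    if len(s) < min_len:
        raise SignalQualityError(
            f"window of {len(s)} samples too short for HR (needs >= {min_len} at low={low} Hz)"
        )
    est = VitalsEstimate(window=pulse.window)
    if np.allclose(s, s[0]):
        return est.invalidate("flat_spectrum")
    freqs, mag = _padded_spectrum(s - s.mean(), fs)
    in_band = (freqs >= low) & (freqs <= high)
    if not in_band.any() or not mag[in_band].max() > 0:
        return est.invalidate("flat_spectrum")
    band_idx = np.flatnonzero(in_band)
    k = band_idx[int(np.argmax(mag[band_idx]))]
    f_h = float(freqs[k])
    # quadratic (parabolic) refinement on log-magnitude neighbours
    if 0 < k < len(mag) - 1 and mag[k - 1] > 0 and mag[k + 1] > 0:
        a, b, c = np.log(mag[k - 1]), np.log(mag[k]), np.log(mag[k + 1])
        denom = a - 2 * b + c
        if denom != 0:
            shift = 0.5 * (a - c) / denom
            f_h += float(np.clip(shift, -1, 1)) * (freqs[1] - freqs[0])
    f_h = float(np.clip(f_h, low, high))
    est.f_h = f_h
    est.hr_bpm = 60.0 * f_h
    return est


def compute_snr(
    pulse: ChrominancePulse,
    fs: float,
    f_h: float,
    band: Tuple[float, float] = DEFAULT_BAND,
) -> float:
    """Fundamental + first-harmonic power over remaining in-band power."""
    low, high = band
    if not (low <= f_h <= high):
        raise SignalQualityError(f"f_h={f_h} outside band {band}")
    s = np.asarray(pulse.s, dtype=float)
    freqs, mag = _padded_spectrum(s - s.mean(), fs)
    power = mag ** 2
    in_band = (freqs >= low) & (freqs <= high)
    total = power[in_band].sum()
    if total <= 0:
        return 0.0
    halfwidth = max(SNR_MASK_MIN_HALFWIDTH_HZ, fs / len(s))  # 1/T for a T-second window
    mask = np.zeros_like(in_band)
    for centre in (f_h, 2.0 * f_h):
        mask |= np.abs(freqs - centre) <= halfwidth
    sig = power[mask & in_band].sum()
    noise = total - sig
    if noise <= 0:
        return float(np.inf)
    return float(sig / noise)


def spo2_components(trace: RGBTrace, start: int = 0, stop: Optional[int] = None) -> SpO2Components:
    """Window DC/AC decomposition of the raw red and blue channels."""
    stop = len(trace) if stop is None else stop
    red = trace.red[start:stop]
    blue = trace.blue[start:stop]
    if len(red) == 0:
        raise SignalQualityError("empty SpO2 window")
    return SpO2Components(
        dc_red=float(np.mean(red)),
        ac_red=float(np.std(red)),
        dc_blue=float(np.mean(blue)),
        ac_blue=float(np.std(blue)),
    )


def ratio_of_ratios(components: SpO2Components) -> float:
    return (components.ac_red / components.dc_red) / (components.ac_blue / components.dc_blue)


def estimate_spo2(
    components: SpO2Components,
    cal: SpO2Calibration = SpO2Calibration(),
) -> Tuple[Optional[float], bool, Optional[str]]:
    """``(spo2_pct, clamped, reason)`` from a DC/AC decomposition.

    ``reason`` is None on success, else ``"dark_frame"`` or
    ``"no_blue_pulsatility"``.
    """
    if components.dc_red <= 0 or components.dc_blue <= 0:
        return None, False, "dark_frame"
    if components.ac_blue <= 0:
        return None, False, "no_blue_pulsatility"
    r = ratio_of_ratios(components)
    raw = cal.A - cal.B * r
    lo, hi = cal.clamp
    clamped = raw < lo or raw > hi
    return float(np.clip(raw, lo, hi)), clamped, None
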