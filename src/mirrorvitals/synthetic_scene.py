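"""Synthetic facial-ROI scenes with known cardiac ground truth.

Generates RGB traces (and optionally frame sequences whose spatial channel
means follow the same model) of the form::

    channel_c(t) = base_c + ac_c * sin(2 pi hr_hz t + phase_c)
                   + harmonic2 * ac_c * sin(2 pi 2 hr_hz t + 2 phase_c)
                   + drift_amp * sin(2 pi drift_hz t) + noise

so heart rate, the encoded ratio-of-ratios, and hence the expected SpO2
are all known analytically.  Everything is driven by a single seeded RNG
and is bit-reproducible.

``phase_c`` is zero for red and blue and ``green_phase_rad`` (default
0.6 rad) for green.  If all three channels carried an identical waveform,
the filtered chrominance pair would be exactly proportional and the
skin-tone-normalized pulse ``S = Xf - alpha Yf`` would vanish identically;
a slight green-channel phase lead (which real skin exhibits) keeps the
chrominance pair linearly independent without touching the red/blue
AC/DC ratios that encode SpO2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np

from .errors import ConfigurationError
from .signal_core import FaceObservation, RGBTrace
from .vitals import SpO2Calibration


@dataclass(frozen=True)
class SceneConfig:
    fs: float = 30.0
    duration_s: float = 60.0
    hr_hz: float = 1.3
    base_rgb: Tuple[float, float, float] = (150.0, 110.0, 90.0)
    ac_rgb: Tuple[float, float, float] = (1.5, 2.0, 1.5)
    noise_sd: float = 0.0
    drift_amp: float = 0.0
    drift_hz: float = 0.1
    frame_shape: Tuple[int, int] = (16, 16)
    seed: int = 0
    harmonic2: float = 0.0  # relative amplitude of the 2*hr_hz component
    green_phase_rad: float = 0.6  # green-channel pulse phase lead (see module docstring)

    def validate(self) -> "SceneConfig":
        if not self.duration_s > 0:
            raise ConfigurationError(f"duration_s must be positive, got {self.duration_s}")
        if not (0 < self.hr_hz < self.fs / 2):
            raise ConfigurationError(
                f"hr_hz must lie in (0, fs/2)=(0, {self.fs / 2}), got {self.hr_hz}"
            )
        if any(b <= 0 for b in self.base_rgb):
            raise ConfigurationError(f"base_rgb components must be positive, got {self.base_rgb}")
        if any(a < 0 for a in self.ac_rgb):
            raise ConfigurationError(f"ac amplitudes must be >= 0, got {self.ac_rgb}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.frame_shape[0] <= 0 or self.frame_shape[1] <= 0:
            raise ConfigurationError(f"frame_shape must be positive, got {self.frame_shape}")
        return self


@dataclass(frozen=True)
class GroundTruth:
    hr_bpm: float
    ratio_of_ratios: Optional[float]
    spo2_expected: Optional[float]
    seed: int


def _ground_truth(config: SceneConfig, cal: SpO2Calibration) -> GroundTruth:
    ac_r, _, ac_b = config.ac_rgb
    base_r, _, base_b = config.base_rgb
    if ac_b > 0:
        ror = (ac_r / base_r) / (ac_b / base_b)
        spo2 = float(np.clip(cal.A - cal.B * ror, *cal.clamp))
    else:
        ror = None
        spo2 = None
    return GroundTruth(
        hr_bpm=config.hr_hz * 60.0, ratio_of_ratios=ror,
        spo2_expected=spo2, seed=config.seed,
    )


def _channel_means(config: SceneConfig) -> np.ndarray:
    """Noise-free (N, 3) channel means for the configured scene."""
    n = int(round(config.fs * config.duration_s))
    t = np.arange(n) / config.fs
    drift = config.drift_amp * np.sin(2 * np.pi * config.drift_hz * t)
    phases = (0.0, config.green_phase_rad, 0.0)
    out = np.empty((n, 3))
    for c in range(3):
        pulse = np.sin(2 * np.pi * config.hr_hz * t + phases[c])
        if config.harmonic2:
            pulse = pulse + config.harmonic2 * np.sin(
                2 * np.pi * 2 * config.hr_hz * t + 2 * phases[c]
            )
        out[:, c] = config.base_rgb[c] + config.ac_rgb[c] * pulse + drift
    return out


def generate_rgb_trace(
    config: SceneConfig,
    cal: SpO2Calibration = SpO2Calibration(),
) -> Tuple[RGBTrace, GroundTruth]:
    """Deterministic synthetic trace plus its analytic ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    values = _channel_means(config)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    trace = RGBTrace(fs=config.fs, values=values)
    return trace, _ground_truth(config, cal)


def generate_frame_sequence(
    config: SceneConfig,
    cal: SpO2Calibration = SpO2Calibration(),
) -> Tuple[List[np.ndarray], List[FaceObservation], GroundTruth]:
    """Uniform skin-patch frames whose spatial means follow the trace model.

    Pixel noise is i.i.d. per pixel, so the spatial average reconstructs
    the noise-free trace to within ``noise_sd / sqrt(H*W)``.  The ROI
    sidecar covers the full frame with confidence 1.0.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    means = _channel_means(config)
    h, w = config.frame_shape
    frames = []
    for i in range(len(means)):
        frame = np.broadcast_to(means[i], (h, w, 3)).copy()
        if config.noise_sd > 0:
            frame += rng.normal(0.0, config.noise_sd, size=frame.shape)
        frames.append(frame)
    roi = FaceObservation(box=(0, 0, w, h), confidence=1.0)
    rois = [roi] * len(frames)
    return frames, rois, _ground_truth(config, cal)


def generate_reference_series(
    config: SceneConfig,
    jitter_sd: float = 0.0,
    timestamps: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Emulated contact-sensor HR series: truth plus Gaussian jitter.

    ``timestamps`` should be the estimate window end-times to align with;
    defaults to one sample per second over the scene duration.
    """
    config.validate()
    if jitter_sd < 0:
        raise ConfigurationError(f"jitter_sd must be >= 0, got {jitter_sd}")
    if timestamps is None:
        timestamps = np.arange(1.0, config.duration_s + 0.5)
    timestamps = np.asarray(timestamps, dtype=float)
    rng = np.random.default_rng(config.seed + 1)  # decorrelated from scene noise
    bpm = np.full(len(timestamps), config.hr_hz * 60.0)
    if jitter_sd > 0:
        bpm = bpm + rng.normal(0.0, jitter_sd, size=len(bpm))
    return timestamps, bpm


def config_for_spo2(
    target_pct: float,
    base: SceneConfig = SceneConfig(),
    cal: SpO2Calibration = SpO2Calibration(),
) -> SceneConfig:
    """Adjust the red AC amplitude so the scene encodes a target SpO2."""
    r = (cal.A - target_pct) / cal.B
    if r <= 0:
        raise ConfigurationError(f"target {target_pct}% implies non-positive ratio {r}")
    base_r, _, base_b = base.base_rgb
    _, ac_g, ac_b = base.ac_rgb
    if ac_b <= 0:
        raise ConfigurationError("base config needs positive blue AC amplitude")
    ac_r = r * (ac_b / base_b) * base_r
    return replace(base, ac_rgb=(ac_r, ac_g, ac_b))


def config_for_ratio(
    ratio: float,
    base: SceneConfig = SceneConfig(),
) -> SceneConfig:
    """Adjust the red AC amplitude so the scene encodes a target ratio-of-ratios."""
    if ratio <= 0:
        raise ConfigurationError(f"ratio must be positive, got {ratio}")
    base_r, _, base_b = base.base_rgb
    _, ac_g, ac_b = base.ac_rgb
    if ac_b <= 0:
        raise ConfigurationError("base config needs positive blue AC amplitude")
    ac_r = ratio * (ac_b / base_b) * base_r
    return replace(base, ac_rgb=(ac_r, ac_g, ac_b))
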