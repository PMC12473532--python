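"""Validated application configuration (JSON file + flag overrides)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from ..errors import ConfigurationError
from ..streaming_session import SessionConfig
from ..vitals import SpO2Calibration


class AppConfig(BaseModel):
    """All tunables with their documented defaults; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    band_low_hz: float = 0.6
    band_high_hz: float = 4.0
    fir_order: Optional[int] = None
    window_s: float = 2.0
    stride_s: float = 1.0
    stabilization_s: float = 26.0
    min_valid_s: float = 8.0
    snr_gate: float = 0.7
    face_conf_gate: float = 0.70
    spo2_A: float = 125.0
    spo2_B: float = 26.0
    spo2_clamp: Tuple[float, float] = (0.0, 100.0)
    affect_votes: int = 30
    seed: int = 0
    language: str = "en"

    @model_validator(mode="after")
    def _check(self):
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("band edges must satisfy 0 < low < high")
        if self.language not in ("en", "ko"):
            raise ValueError("language must be 'en' or 'ko'")
        return self

    @classmethod
    def load(cls, path) -> "AppConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
        try:
            return cls(**payload)
        except ValidationError as exc:
            raise ConfigurationError(f"invalid config {path}: {exc}") from exc

    def session_config(self) -> SessionConfig:
        return SessionConfig(
            window_s=self.window_s,
            stride_s=self.stride_s,
            stabilization_s=self.stabilization_s,
            min_valid_s=self.min_valid_s,
            snr_gate=self.snr_gate,
            face_conf_gate=self.face_conf_gate,
            hr_band=(self.band_low_hz, self.band_high_hz),
            affect_votes=self.affect_votes,
            fir_order=self.fir_order,
            spo2_cal=SpO2Calibration(A=self.spo2_A, B=self.spo2_B, clamp=self.spo2_clamp),
        )
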