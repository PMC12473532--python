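"""Assemble the bilingual wellness-chatbot prompt from a vitals + affect
snapshot.  Transport to any LLM backend is a caller-supplied callable; a
canned stub ships for tests."""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

from .errors import ChatError, ConfigurationError, ContextError

SYSTEM_TEMPLATE_EN = (
    "You are a chatbot integrated into a smart mirror system. This smart mirror "
    "uses a camera to extract real-time estimates of the user’s age, emotion, "
    "heart rate, and oxygen saturation. These values are AI-based estimations and "
    "may not always be accurate—please consider this when responding. Provide a "
    "short health and wellness summary (max 3 sentences), identify possible signs "
    "of stress, fatigue, or health concerns, and offer a simple lifestyle or "
    "recovery suggestion."
)

USER_TEMPLATE_EN = (
    "User profile: Age: {age}, Emotion: {expression}, Heart Rate: {bpm} BPM, SpO2: {spo2}%."
)

# Korean scaffolding is a documented translation (the published template is
# English-only); slot order mirrors the English template.
SYSTEM_TEMPLATE_KO = (
    "당신은 스마트 미러 시스템에 통합된 "
    "챗봇입니다. 이 스마트 미러는 카메라로 "
    "사용자의 나이, 감정, 심박수, 산소 포화도를 "
    "실시간으로 추정합니다. 이 값들은 AI 기반 "
    "추정치이므로 항상 정확하지 않을 수 있으니 "
    "응답 시 이를 고려하세요. 건강 및 웰빙 요약을 "
    "최대 3문장으로 제공하고, 스트레스·피로·건강 "
    "이상 징후를 식별하며, 간단한 생활 습관 또는 "
    "회복 제안을 제시하세요."
)

USER_TEMPLATE_KO = (
    "사용자 프로필: 나이: {age}, 감정: {expression}, "
    "심박수: {bpm} BPM, SpO2: {spo2}%."
)

_TEMPLATES = {
    "en": (SYSTEM_TEMPLATE_EN, USER_TEMPLATE_EN),
    "ko": (SYSTEM_TEMPLATE_KO, USER_TEMPLATE_KO),
}


@dataclass(frozen=True)
class PromptContext:
    age_bucket: Optional[str] = None
    emotion: Optional[str] = None
    hr_bpm: Optional[int] = None
    spo2_pct: Optional[int] = None
    language: str = "en"

    def __post_init__(self):
        if self.language not in _TEMPLATES:
            raise ConfigurationError(f"language must be one of {sorted(_TEMPLATES)}")
        if self.hr_bpm is not None and self.hr_bpm <= 0:
            raise ConfigurationError("hr_bpm must be positive")
        if self.spo2_pct is not None and not (0 <= self.spo2_pct <= 100):
            raise ConfigurationError("spo2_pct must lie in [0, 100]")


def build_prompt(ctx: PromptContext) -> Tuple[str, str]:
    """``(system_part, user_part)`` with all four slots interpolated.

    Missing slots raise :class:`ContextError` naming them (the heart-rate
    slot is ``bpm``, the emotion slot ``expression``, matching the
    template's slot names).
    """
    missing = []
    if ctx.age_bucket is None:
        missing.append("age")
    if ctx.emotion is None:
        missing.append("expression")
    if ctx.hr_bpm is None:
        missing.append("bpm")
    if ctx.spo2_pct is None:
        missing.append("spo2")
    if missing:
        raise ContextError(missing)
    system, user = _TEMPLATES[ctx.language]
    return system, user.format(
        age=ctx.age_bucket, expression=ctx.emotion, bpm=ctx.hr_bpm, spo2=ctx.spo2_pct
    )


def send_to_chat(prompt: Tuple[str, str], transport: Callable[[str, str], str]) -> Tuple[str, float]:
    """Send (system, user) through a transport callable.

    Returns ``(response_text, latency_s)``.  Any transport exception is
    wrapped in :class:`ChatError`; there is no retry.
    """
    system, user = prompt
    start = time.monotonic()
    try:
        response = transport(system, user)
    except Exception as exc:
        raise ChatError(f"chat transport failed: {exc}") from exc
    return response, time.monotonic() - start


def stub_transport(response: Optional[str] = None) -> Callable[[str, str], str]:
    """Canned transport: echoes the user part, or returns a fixed text."""

    def _transport(system: str, user: str) -> str:
        return user if response is None else response

    return _transport
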