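"""Exception hierarchy shared across the package."""


class MirrorVitalsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirrorVitalsError):
    """A configuration value violates a documented invariant."""


class SignalQualityError(MirrorVitalsError):
    """Input signal is unusable for the requested operation (non-fatal per frame)."""


class EmptyInputError(MirrorVitalsError):
    """No usable samples were supplied."""


class StreamError(MirrorVitalsError):
    """Frame stream violates its timing contract."""


class GeometryError(MirrorVitalsError):
    """Landmark geometry is degenerate or inconsistent."""


class ClassificationError(MirrorVitalsError):
    """Embedding classification preconditions violated."""


class ContextError(MirrorVitalsError):
    """Prompt context is missing required slots."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing prompt context fields: {', '.join(self.missing)}")


class ChatError(MirrorVitalsError):
    """Transport to the chat backend failed."""


class AlignmentError(MirrorVitalsError):
    """Two timestamped series share no pairable samples."""


class ParseError(MirrorVitalsError):
    """A text input file is malformed."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
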