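"""Exception hierarchy shared across the toolkit."""


class RpvoltError(Exception):
    """Base class for all toolkit errors."""


class InvalidSpecError(RpvoltError, ValueError):
    """A waveform, preprocessing, or session specification is inconsistent."""


class ConvergenceError(RpvoltError, RuntimeError):
    """An iterative fit (NIPALS inner loop) failed to converge."""


class NotFittedError(RpvoltError, RuntimeError):
    """An operation requires a fitted model or scaler that is absent."""


class StreamError(RpvoltError, ValueError):
    """A scan stream cannot satisfy the requested extraction."""
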