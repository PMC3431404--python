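"""Exception hierarchy."""


class IonLoopError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IonLoopError):
    """Invalid configuration (unknown role label, bad option value...)."""


class FormatError(IonLoopError):
    """Structure/trajectory file does not parse under the named dialect."""


class SelectionError(IonLoopError):
    """Selection expression is malformed or resolves to no atoms."""


class ParameterError(IonLoopError):
    """Missing or physically invalid per-atom parameters."""


class AnalysisError(IonLoopError):
    """Domain error raised by an analysis operation (empty profile...)."""
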