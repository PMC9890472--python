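"""Exception hierarchy for the popout pipeline."""


class PopoutError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PopoutError):
    """A parameter violates a structural constraint (band count, list divisibility, ...)."""


class SynthesisError(PopoutError):
    """Audio synthesis impossible with the requested parameters (e.g. formant above Nyquist)."""


class StructuralError(PopoutError):
    """A container (stimulus pool, design, layout) is malformed."""


class AlignmentError(PopoutError):
    """Stimulus and recording clocks or lengths cannot be reconciled."""


class BoundaryError(PopoutError):
    """A requested window falls outside the available recording."""
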