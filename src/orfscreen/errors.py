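"""Typed exceptions shared across the package."""


class OrfScreenError(Exception):
    """Base class for all package errors."""


class ParameterError(OrfScreenError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateDataError(OrfScreenError, ValueError):
    """Input data are degenerate for the requested statistic (e.g. constant
    lengths for a rank correlation, flat viability for a dose-response fit)."""


class OrfMismatchError(OrfScreenError, ValueError):
    """Two tables that must index the same ORF universe do not."""


class PipelineError(OrfScreenError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
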