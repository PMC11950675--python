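"""Exception hierarchy shared across the pipeline.

Three error families map onto the CLI's exit codes: malformed input
files (:class:`FormatError`), violated domain invariants
(:class:`ValidationError`), and statistically degenerate data
(:class:`DegenerateDataError`).
"""


class MacpolarError(Exception):
    """Base class for all package errors."""


class FormatError(MacpolarError):
    """An input file could not be parsed (bad cell, missing header, ...)."""


class ValidationError(MacpolarError):
    """Parsed data violates a domain invariant (duplicate id, bad role, ...)."""


class DegenerateDataError(MacpolarError):
    """The data is too degenerate for the requested statistic."""


class EmptyGateError(DegenerateDataError):
    """A gate retained zero events — almost certainly mis-set bounds."""
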