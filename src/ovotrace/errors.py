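"""Exception hierarchy shared across the toolkit."""


class OvotraceError(Exception):
    """Base class for all toolkit errors."""


class FormatError(OvotraceError, ValueError):
    """A file does not conform to the spectra-table layout."""


class ValidationError(OvotraceError, ValueError):
    """Data violates a domain invariant (axis order, label codes, shapes)."""


class ParameterError(OvotraceError, ValueError):
    """An algorithm parameter is out of its admissible range."""


class DegenerateDataError(OvotraceError, ValueError):
    """The data admit no meaningful fit (constant row, all-zero weights...)."""
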