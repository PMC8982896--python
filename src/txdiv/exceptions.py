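"""Exception hierarchy for txdiv.

All txdiv-specific failures derive from :class:`TxdivError` so callers can
catch the whole family; each subclass also derives from ``ValueError`` to
behave sensibly in generic code.
"""


class TxdivError(Exception):
    """Base class for all txdiv errors."""


class DataFormatError(TxdivError, ValueError):
    """Malformed or inconsistent input data.

    Messages always name the offending location (gene, sample, column or
    file) so that rejections are actionable.
    """


class DegenerateDataError(TxdivError, ValueError):
    """Input is structurally valid but degenerate for the requested
    computation (e.g. a constant vector where a correlation is needed)."""


class InvalidParameterError(TxdivError, ValueError):
    """A parameter value is outside its allowed range."""
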