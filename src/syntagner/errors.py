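"""Exception hierarchy.

All failures surface as one of these so the CLI can map them to exit codes
(2 for configuration problems, 3 for data problems).
"""


class SyntagnerError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SyntagnerError):
    """Invalid or inconsistent configuration (bad shapes, missing layers, unknown tags)."""


class DataError(SyntagnerError):
    """Malformed or inconsistent input data."""


class ParseError(DataError):
    """A stream could not be parsed; carries location information in the message."""


class AlignmentError(DataError):
    """Annotation layers do not line up with the corpus tokens."""


class ValidationError(DataError):
    """Well-formed input violating a semantic contract (e.g. an illegal BIO tag)."""
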