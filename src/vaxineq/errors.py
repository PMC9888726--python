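"""Exception hierarchy.

``ValidationError`` covers malformed user input (bad config fields, schema
violations, degenerate groups); anything else escaping the library is an
internal error. The CLI maps the two onto exit codes 1 and 2.
"""


class VaxineqError(Exception):
    """Base class for all package errors."""


class ValidationError(VaxineqError):
    """Invalid input data or configuration."""


class ConfigError(ValidationError):
    """Invalid configuration field; message names the offending field."""


class DegenerateOutcomeError(ValidationError):
    """Concentration indices are undefined when the weighted mean of the
    binary outcome is 0 or 1: the attainable bounds [mu-1, 1-mu] collapse
    to a point, so no index value is meaningful."""
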