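"""Exception hierarchy shared across modules."""


class MzCanvasError(Exception):
    """Base class for all package errors."""


class DataError(MzCanvasError):
    """Malformed, missing, or contract-violating input data."""


class QueryError(MzCanvasError):
    """Rejected or invalid results-store query."""
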