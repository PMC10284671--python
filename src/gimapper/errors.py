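"""Exception hierarchy shared across the package.

All domain errors derive from :class:`GimapperError` so the CLI can map them
to a one-line diagnostic and exit status 1, while programming errors
propagate normally.
"""


class GimapperError(Exception):
    """Base class for all handled domain errors."""


class SchemaError(GimapperError):
    """An input table is missing a required column or has a malformed header."""


class IntegrityError(GimapperError):
    """An input table violates an invariant (e.g. duplicate line IDs)."""


class ParseError(GimapperError):
    """A cell could not be parsed; message carries row/column coordinates."""


class GeneNotFoundError(GimapperError):
    """A requested gene symbol is absent from a matrix."""


class EmptyCohortError(GimapperError):
    """Cohort selection left no cell lines to analyse."""


class NoDataError(GimapperError):
    """No overlapping observations between groups and a data matrix."""
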