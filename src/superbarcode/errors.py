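"""Exception hierarchy shared across the pipeline."""


class BarcodeError(Exception):
    """Base class for all package-specific errors."""


class AlignmentShapeError(BarcodeError):
    """Sequences in an alignment do not all have the same length."""


class IdentityError(BarcodeError):
    """Duplicate or unknown accession / leaf identifiers."""


class FormatError(BarcodeError):
    """A file or sequence does not conform to its expected format."""


class CoordinateError(BarcodeError):
    """A genomic interval is empty, inverted, or out of bounds."""


class ParameterError(BarcodeError):
    """An operation received an invalid parameter value."""


class RootingError(BarcodeError):
    """The requested outgroup does not form a clade in the tree."""


class IncompleteMatrixError(BarcodeError):
    """A distance matrix contains undefined cells where defined ones are required."""
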