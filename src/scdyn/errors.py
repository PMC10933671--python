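"""Named exceptions raised across the package."""


class ScdynError(Exception):
    """Base class for all package errors."""


class LayerShapeMismatchError(ScdynError):
    """New- and old-RNA layers do not have identical shapes."""


class NegativeCountError(ScdynError):
    """A count layer contains negative entries."""


class DuplicateIdentifierError(ScdynError):
    """Gene or cell identifiers are not unique."""


class UnknownAnnotationError(ScdynError):
    """An annotated cell does not exist in the matrix, or a group key is unknown."""


class GeneNotFoundError(ScdynError):
    """A requested gene identifier is absent from the matrix."""


class SignatureGenesMissingError(ScdynError):
    """No gene of a signature is present in the matrix."""


class ConfigError(ScdynError):
    """A run configuration is invalid (missing inputs, inconsistent fields)."""
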