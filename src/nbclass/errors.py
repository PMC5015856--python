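"""Exception hierarchy shared across the package."""


class NBCError(Exception):
    """Base class for all package errors."""


class FormatError(NBCError):
    """A file does not conform to the expected layout (header, columns)."""


class ParseError(FormatError):
    """A cell value could not be interpreted; the message names the location."""


class ValidationError(NBCError):
    """A loaded object violates an invariant (duplicates, empty classes)."""


class AlignmentError(NBCError):
    """Expression matrix and drug-response table share too few cell lines."""


class DomainError(NBCError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class SelectionError(NBCError):
    """Feature selection has no usable candidate genes."""


class TrainingError(NBCError):
    """A model cannot be trained on the given class sample sizes."""


class MetricError(NBCError):
    """A metric is undefined for the given confusion counts or labels."""


class InfeasibilityError(NBCError):
    """A cross-validation split cannot keep both classes in every fold."""


class ConfigError(NBCError):
    """A run configuration contains unknown or invalid keys."""
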