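"""Exception hierarchy shared across the package.

Everything derives from :class:`PhylosymError` so callers can catch one
base class; the leaves distinguish bad identifiers, degenerate inputs,
and design problems the way the individual operations document them.
"""


class PhylosymError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PhylosymError):
    """A file or lineage string could not be parsed."""


class IdentifierError(PhylosymError):
    """Duplicate or otherwise invalid taxon/sample identifiers."""


class LabelError(PhylosymError, KeyError):
    """A referenced label (taxon, leaf, species) is missing."""


class MetadataError(PhylosymError):
    """Sample metadata does not cover the feature table."""


class DegenerateSampleError(PhylosymError):
    """A sample has zero total abundance (or is otherwise unusable)."""


class DegenerateTraitError(PhylosymError):
    """A trait vector is constant or undefined."""


class DepthError(PhylosymError):
    """Rarefaction depth exceeds a sample's total count."""


class SizeError(PhylosymError):
    """Input too small for the requested operation."""


class DesignError(PhylosymError):
    """Statistical design invalid (e.g. a single group in PERMANOVA)."""


class FitError(PhylosymError):
    """Model fitting failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class ConfigError(PhylosymError):
    """Invalid synthetic-data configuration."""


class InputError(PhylosymError):
    """Generic invalid input (mismatched matrices, empty lists, ...)."""
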