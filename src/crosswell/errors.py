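"""Exception hierarchy.

Every stage raises a subclass of :class:`CrosswellError` so the pipeline
driver can abort with a stage-labelled message.
"""


class CrosswellError(Exception):
    """Base class for all crosswell errors."""


class AddressingError(CrosswellError):
    """Malformed or out-of-range well identifier."""


class LayoutError(CrosswellError):
    """Invalid plate layout (role counts, duplicate wells, missing origins)."""


class PanelError(CrosswellError):
    """Invalid reference panel (bad sequences, duplicate entries)."""


class AmbiguousPanelError(PanelError):
    """A trimmed reference sequence is claimed by two different labels."""


class ClassificationError(CrosswellError):
    """sOTU tags incompatible with the panel (e.g. shorter than trim length)."""


class AccountingError(CrosswellError):
    """Read partitioning encountered an unclassified sOTU."""


class MetadataError(CrosswellError):
    """Sample metadata is inconsistent or incomplete."""


class SummaryError(CrosswellError):
    """Group summary requested over an empty group set."""


class PairingError(CrosswellError):
    """Replicate pairing produced zero usable pairs."""


class StatTestError(CrosswellError):
    """Rank test called with invalid group structure."""


class UndefinedDistanceError(CrosswellError):
    """Dissimilarity undefined (both vectors empty)."""


class ParameterError(CrosswellError):
    """Invalid simulation or analysis parameter."""


class FormatError(CrosswellError):
    """Malformed input file (counts, metadata, references)."""


class ConfigError(CrosswellError):
    """Invalid or incomplete pipeline configuration."""
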