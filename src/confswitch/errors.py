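"""Exception hierarchy for the confswitch pipeline.

Every stage raises a subclass of :class:`ConfswitchError` so the CLI can map
failures onto its documented exit codes (2 config, 3 data, 4 design
exhausted).
"""


class ConfswitchError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(ConfswitchError):
    """Invalid or inconsistent run configuration."""


class StructureFormatError(ConfswitchError):
    """A coordinate or sequence file does not parse under its standard."""


class CapacityError(ConfswitchError):
    """Output format cannot represent the data (e.g. >9999 residues/chain)."""


class MsaFormatError(ConfswitchError):
    """Alignment rows are inconsistent after projection onto the query."""


class MaskedColumnError(ConfswitchError):
    """A gap-masked column was requested for pair scoring."""


class InsufficientDataError(ConfswitchError):
    """Too few effective sequences to estimate covariation."""


class TopologyError(ConfswitchError):
    """Membrane frame or TM-helix annotation failed."""


class MappingError(ConfswitchError):
    """Residue numbering could not be reconciled between inputs."""


class DesignError(ConfswitchError):
    """No admissible mutation sites remain."""


class AlignmentError(ConfswitchError):
    """Structure superposition has too few (or unalignable) common residues."""


class ClassificationError(ConfswitchError):
    """Gate regions are empty; conformational state cannot be called."""


class PredictorError(ConfswitchError):
    """The external (or mock) structure predictor failed its contract."""
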