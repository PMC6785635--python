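"""Exception hierarchy shared across the package."""


class NpfCavityError(Exception):
    """Base class for all package-specific errors."""


class AlignmentShapeError(NpfCavityError):
    """Raised when sequences in an alignment do not share one length."""


class AlphabetError(NpfCavityError):
    """Raised when a sequence contains a symbol outside the accepted alphabet."""


class AnchorError(NpfCavityError):
    """Raised when a position anchor cannot be resolved on the reference."""


class ConfigurationError(NpfCavityError):
    """Raised for unresolvable position labels or mismatched configurations."""


class PairingError(NpfCavityError):
    """Raised when a superposition pairing cannot be resolved."""


class ProbeError(NpfCavityError):
    """Raised when a cavity probe atom cannot be resolved."""


class MissingLigandError(NpfCavityError):
    """Raised when a ligand-proximity selection is requested without a ligand."""


class EncodingError(NpfCavityError):
    """Raised when a residue has no descriptor entry."""


class NormalizationError(NpfCavityError):
    """Raised when the reference or mock group is missing from a batch."""


class ClassificationError(NpfCavityError):
    """Raised when a compound has no known permeability class."""
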