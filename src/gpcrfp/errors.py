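"""Exception hierarchy.

Every error raised by this package derives from :class:`GpcrfpError` so
callers (and the CLI) can distinguish validation failures from bugs.
"""


class GpcrfpError(Exception):
    """Base class for all package errors."""


class PDBParseError(GpcrfpError):
    """A coordinate file could not be parsed."""


class TopologyMismatchError(GpcrfpError):
    """Models of a multi-model file do not share one atom list."""


class SelectionError(GpcrfpError):
    """A selection expression could not be resolved."""


class BWLookupError(SelectionError):
    """A Ballesteros-Weinstein label is absent from the residue map."""


class DegenerateGeometryError(GpcrfpError):
    """Coincident or collinear points where a torsion/frame is required."""


class UnsupportedChiError(GpcrfpError):
    """The requested chi index is not defined for this residue type."""


class NoSideChainError(GpcrfpError):
    """A side-chain metric was requested for a residue without one (Gly)."""


class InsufficientPairsError(GpcrfpError):
    """Fewer than three paired atoms available for superposition."""


class InfeasibleSpecError(GpcrfpError):
    """A synthetic-bundle specification produces clashing helices."""


class EmptySeriesError(GpcrfpError):
    """A distribution was requested over a series with no valid values."""


class ValidationError(GpcrfpError):
    """An input matrix/array violates a structural precondition."""


class IncomparableReportsError(GpcrfpError):
    """Two fingerprint reports were produced under different configs."""


class ConfigurationError(GpcrfpError):
    """Required configuration (e.g. a BW label) is missing."""
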