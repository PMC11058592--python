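"""Exception hierarchy.

Every user-facing failure mode raises a named subclass of
:class:`LoopshiftError`, so callers (and the CLI) can distinguish
validation problems from computation problems.
"""


class LoopshiftError(Exception):
    """Base class for all package errors."""


class ConfigError(LoopshiftError):
    """Invalid configuration or specification values."""


class PDBFormatError(LoopshiftError):
    """A structure file could not be parsed."""


class ModelNotFoundError(PDBFormatError):
    """Requested MODEL index does not exist in a PDB file."""


class InsertionCodeError(PDBFormatError):
    """Residue insertion codes are present; (chain, residue_index) keys
    would be ambiguous, so these files are rejected."""


class AtomCountMismatchError(LoopshiftError):
    """A frame's atom count disagrees with the topology."""


class FrameNumberingError(LoopshiftError):
    """Tabular trajectory frames are not contiguously numbered."""


class SelectionError(LoopshiftError):
    """An atom/residue selection refers to atoms missing from the topology."""


class AlignmentError(LoopshiftError):
    """Two per-frame series or residue axes that must be aligned are not."""


class DegenerateGeometryError(LoopshiftError):
    """Superposition attempted on fewer than 3 atoms or a collinear set."""


class EmptySeriesError(LoopshiftError):
    """An operation received an empty series or selection."""


class NoBarrierError(LoopshiftError):
    """A free-energy profile has no interior maximum between two minima."""
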