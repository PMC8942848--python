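"""Exception hierarchy.

All package errors derive from :class:`DimerStateError` so callers can catch
one base class at CLI boundaries.
"""


class DimerStateError(Exception):
    """Base class for all package errors."""


class FormatError(DimerStateError):
    """A structure or trajectory file could not be parsed."""


class EmptyStructureError(DimerStateError):
    """A parsed file contained no atoms."""


class DimerRequiredError(DimerStateError):
    """An operation needs exactly two assigned protomers."""


class ConfigurationError(DimerStateError):
    """Invalid configuration: overlapping segments, missing radii/parameters."""


class PairingError(DimerStateError):
    """Point sets of unequal length were passed to a paired operation."""


class DegenerateGeometryError(DimerStateError):
    """Geometry too degenerate to define the requested quantity."""


class NoCommonResiduesError(DimerStateError):
    """Two structures share no residues under the requested selection."""


class SeedBuriedError(DimerStateError):
    """A pocket seed point lies inside the protein volume."""


class TopologyError(DimerStateError):
    """Trajectory atom count does not match its topology."""


class FrameBoundaryError(DimerStateError):
    """A trajectory file ended mid-frame."""
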