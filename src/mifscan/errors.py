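"""Exception hierarchy for mifscan.

Every error raised on purpose derives from :class:`MifScanError` so callers
(and the CLI) can distinguish usage/data problems from genuine bugs.
"""


class MifScanError(Exception):
    """Base class for all mifscan errors."""


class ParseError(MifScanError):
    """A structure or grid file could not be parsed; names the offending line."""


class StructureError(MifScanError):
    """A Structure violates an invariant (missing CA, empty, non-contiguous residues)."""


class GeometryError(MifScanError):
    """Atoms fall outside (or hug) the grid box."""


class SolverError(MifScanError):
    """The iterative LPBE solve diverged; carries the residual trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


class ClassificationError(MifScanError):
    """An atom could not be assigned an apolar/polar class in strict mode."""


class DegenerateSkinError(MifScanError):
    """A skin mask selected fewer grid points than the configured minimum."""


class UndefinedSIError(MifScanError):
    """Both fields vanish on the mask: the Hodgkin index is undefined, not zero."""


class AlignmentError(MifScanError):
    """Structures have unequal residue counts; a residue mapping is required."""


class FlaggedEntriesError(MifScanError):
    """A similarity matrix contains undefined entries where a full matrix is required."""


class ConfigError(MifScanError):
    """A pipeline run configuration failed validation."""
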