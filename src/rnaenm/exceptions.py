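"""Exception hierarchy for rnaenm.

All package errors derive from :class:`RnaEnmError` so callers (and the CLI)
can distinguish model/input problems from programming errors.
"""


class RnaEnmError(Exception):
    """Base class for all rnaenm errors."""

    #: short machine-greppable reason code, overridden by subclasses
    code = "ERROR"


class ParseError(RnaEnmError):
    """Structure or profile text could not be parsed."""

    code = "PARSE"


class ModelIndexError(RnaEnmError):
    """Requested model index beyond the models present in the file."""

    code = "MODEL_RANGE"


class EmptySelectionError(RnaEnmError):
    """A bead scheme selected zero atoms from the input structure."""

    code = "EMPTY_SELECTION"


class DegenerateGeometryError(RnaEnmError):
    """Coincident beads or zero-length vectors where geometry is required."""

    code = "DEGENERATE_GEOMETRY"


class ConnectivityError(RnaEnmError):
    """The elastic network is disconnected (more than six zero modes)."""

    code = "CONNECTIVITY"


class ReductionError(RnaEnmError):
    """The discarded block of the Hessian is numerically singular."""

    code = "REDUCTION"


class CutoffNotFoundError(RnaEnmError):
    """No cutoff on the scan grid yields exactly six zero modes."""

    code = "CUTOFF_NOT_FOUND"


class AlignmentError(RnaEnmError):
    """Superposition subset is degenerate (fewer than 3 non-collinear sites)."""

    code = "ALIGNMENT"


class ContractError(RnaEnmError):
    """An operation was called on input violating its documented contract."""

    code = "CONTRACT"


class UndefinedMeasureError(RnaEnmError):
    """A similarity or correlation measure is undefined for this input."""

    code = "UNDEFINED_MEASURE"


class SchemeError(RnaEnmError):
    """The bead scheme lacks a role required by the requested operation."""

    code = "SCHEME"


class InsufficientOverlapError(RnaEnmError):
    """Fewer than three residues matched between profile and reactivities."""

    code = "INSUFFICIENT_OVERLAP"


class PackingError(RnaEnmError):
    """Random point generation failed to satisfy the separation constraint."""

    code = "PACKING"
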