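"""Exception hierarchy shared by the whole suite.

Each class carries the process exit code the command-line front ends use:
2 usage, 3 input parsing, 4 mapping/validation, 5 external-tool failure.
"""


class CCD2MDError(Exception):
    """Base class for all suite errors."""

    exit_code = 1


class UsageError(CCD2MDError):
    """Bad command-line arguments or incompatible flag combinations."""

    exit_code = 2


class ParseError(CCD2MDError):
    """A structure or topology file could not be parsed."""

    exit_code = 3


class UnsupportedFormatError(ParseError):
    """Format tag not recognised."""


class RangeError(CCD2MDError):
    """A value does not fit the fixed-column width of the output format."""

    exit_code = 3


class ValidationError(CCD2MDError):
    """Mapping database or cross-file consistency violation."""

    exit_code = 4


class NotFoundError(ValidationError):
    """A requested residue or ligand is absent."""


class IncompleteLigandError(ValidationError):
    """A matched ligand's atom set differs from its mapping's atom set."""

    def __init__(self, ligand, missing=(), extra=()):
        self.ligand = ligand
        self.missing = sorted(missing)
        self.extra = sorted(extra)
        super().__init__(
            f"ligand {ligand!r}: missing atoms {self.missing}, extra atoms {self.extra}"
        )


class MultiplicityError(ValidationError):
    """Zero or more than one copy of a ligand where exactly one is required."""


class ConflictError(ValidationError):
    """A user component name collides with an unrelated force-field name."""


class ChainAllocationError(ValidationError):
    """No free chain identifier is left for the ligand chain."""


class ExternalToolError(CCD2MDError):
    """An external adapter (pdb2gmx, Martinize2, MemPrO, CG2AT) failed."""

    exit_code = 5
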