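"""Exception hierarchy shared by all pipeline stages.

The CLI maps these onto distinct exit codes: input errors (bad files,
malformed records, missing systems) exit 2, configuration errors exit 3,
numerical errors (degenerate geometry, singularities) exit 4.
"""


class PkaffinityError(Exception):
    """Base class for all package errors."""


class InputError(PkaffinityError):
    """A problem with user-supplied data (files, tables, selections)."""

    exit_code = 2


class PDBParseError(InputError):
    """A malformed PDB record; the message names the offending line."""


class ParameterLookupError(InputError):
    """Force-field parameters missing for one or more atoms."""

    def __init__(self, missing):
        self.missing = list(missing)
        pairs = ", ".join(f"({r}, {a})" for r, a in self.missing)
        super().__init__(f"no parameters for atom(s): {pairs}")


class SelectionError(InputError):
    """An atom selection that matches nothing or cannot be parsed."""


class DomainError(InputError):
    """A value outside the mathematical domain of an operation."""


class ConfigError(PkaffinityError):
    """Inconsistent or incomplete run configuration."""

    exit_code = 3


class NumericalError(PkaffinityError):
    """Degenerate geometry or a numerical singularity."""

    exit_code = 4
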