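"""Exception hierarchy for the arteriovenous kinetics pipeline.

All package errors derive from :class:`AVKineticsError` so callers can catch
the whole family; validation problems (bad files, bad configs) are kept
distinct from physiologically impossible measurements (no indicator dilution,
zero precursor enrichment) so a driver can map them to different exit codes.
"""


class AVKineticsError(Exception):
    """Base class for all errors raised by this package."""


class InvalidMeasurementError(AVKineticsError, ValueError):
    """A raw measurement violates its physical bounds (e.g. negative ion ratio)."""


class UnitError(AVKineticsError, ValueError):
    """An unrecognised or inconsistent unit tag."""


class SchemaError(AVKineticsError, ValueError):
    """A sample table or config file does not match the expected dialect."""


class InsufficientDataError(AVKineticsError, ValueError):
    """Too few time points for the requested plateau window."""


class MissingSampleError(AVKineticsError, ValueError):
    """No sample exists at the requested time point."""


class NoDilutionError(AVKineticsError, ValueError):
    """Venous indicator concentration does not exceed arterial: plasma flow
    is undefined (catheter placement or steady-state failure)."""


class DivisionGuardError(AVKineticsError, ZeroDivisionError):
    """A tracer-dilution denominator (an enrichment) is zero or negative."""


class IncompleteInputError(AVKineticsError, ValueError):
    """An animal is missing required analyte/site steady states.

    ``missing`` lists the gaps as ``"analyte@site"`` strings.
    """

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            "incomplete steady-state input; missing: " + ", ".join(self.missing)
        )


class InfeasibleTruthError(AVKineticsError, ValueError):
    """A simulated ground truth implies a negative venous concentration or an
    enrichment outside [0, 1)."""


class ConfigError(AVKineticsError, ValueError):
    """Invalid run or simulation configuration."""


class UndefinedCorrelationError(AVKineticsError, ValueError):
    """Pearson correlation requested on a constant column."""

    def __init__(self, column):
        self.column = column
        super().__init__(f"correlation undefined for constant column {column!r}")


class AlignmentError(AVKineticsError, ValueError):
    """Truth registry and estimate table do not share the same animal ids."""
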