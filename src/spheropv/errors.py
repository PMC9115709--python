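"""Exception hierarchy for the spheropv pipeline.

Every stage raises a subclass of :class:`SpheroPVError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class SpheroPVError(Exception):
    """Base class for all spheropv errors."""


class SchemaError(SpheroPVError):
    """A table is missing a mandatory column or has an unusable header."""


class ParseError(SpheroPVError):
    """A cell could not be parsed; message names the row and column."""


class ValidationError(SpheroPVError):
    """A record violates a hard invariant (bounds, duplicates, vocabulary)."""


class MissingDataError(SpheroPVError):
    """An operation needs a descriptor/field that is absent from the record."""

    def __init__(self, fields, context=""):
        if isinstance(fields, str):
            fields = [fields]
        self.fields = list(fields)
        msg = f"missing required field(s): {', '.join(self.fields)}"
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


class StructureError(SpheroPVError):
    """A molecular structure string could not be parsed."""


class CapabilityError(SpheroPVError):
    """An optional backend (e.g. a cheminformatics toolkit) is unavailable."""


class MeasurementError(SpheroPVError):
    """A plate readout is physically impossible (e.g. non-positive control)."""


class PairingError(SpheroPVError):
    """Efficacy values could not be matched across spheroid compositions."""


class FeasibilityError(SpheroPVError):
    """A simulation target cannot be realized within physical bounds."""


class InsufficientDataError(SpheroPVError):
    """Too few observations for the requested statistical operation."""


class CollinearityError(SpheroPVError):
    """The regression design matrix is rank deficient."""

    def __init__(self, columns, msg=None):
        self.columns = list(columns)
        super().__init__(
            msg or f"rank-deficient design; dependent column(s): {', '.join(self.columns)}"
        )


class NumericalError(SpheroPVError):
    """A computation produced or received a non-finite value."""


class NoObjectError(SpheroPVError):
    """A mask image contains no foreground object."""


class ReportingError(SpheroPVError):
    """A report was requested for an incomplete run."""
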