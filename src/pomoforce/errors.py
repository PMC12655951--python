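"""Exception hierarchy for the penetration-test pipeline."""


class PomoforceError(Exception):
    """Base class for all package errors."""


class FormatError(PomoforceError):
    """A delimited file is missing required columns or is malformed."""


class DataError(PomoforceError):
    """A file parsed but its content violates a data contract."""


class ContactError(DataError):
    """The force signal never reaches the contact threshold."""


class YieldNotFoundError(PomoforceError):
    """Neither the drop detector nor the residual fallback located a yield point."""


class PlateauError(PomoforceError):
    """The plateau averaging window past the rupture point is empty."""


class FitError(PomoforceError):
    """The elastic segment is too short for a least-squares fit."""


class DegenerateDataError(PomoforceError):
    """A statistical test received data with no variation."""


class InfeasibleSpecError(PomoforceError):
    """A simulation spec implies a geometrically impossible curve."""
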