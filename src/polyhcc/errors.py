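"""Exception hierarchy for polyhcc.

Every error raised by the library derives from :class:`PolyhccError` so
callers (and the CLI) can catch one base class.
"""


class PolyhccError(Exception):
    """Base class for all polyhcc errors."""


class ConfigError(PolyhccError):
    """A generator or pipeline configuration field is invalid."""


class UncallableProbeError(PolyhccError):
    """No nonzero spot count is available for a probe, so its predominant
    copy number cannot be determined."""


class UncallableTumorError(PolyhccError):
    """A tumor's ploidy cannot be called (empty input or an uncallable probe)."""


class EmptyGateError(PolyhccError):
    """The cytometry gate (tumor, HNF4a+, Ki-67-) selected no nuclei."""


class InsufficientReferenceError(PolyhccError):
    """Too few diploid reference nuclei to estimate the 2C intensity mode."""


class EmptyGroupError(PolyhccError):
    """A group comparison received an empty group."""


class InputError(PolyhccError):
    """A statistical routine received invalid input."""


class GradeValidationError(PolyhccError):
    """An IHC grade string is not one of the allowed ordinal values."""


class JoinError(PolyhccError):
    """Two per-tumor tables do not share the same tumor_id set."""


class TableValidationError(PolyhccError):
    """A delimited-text table failed schema validation.

    Carries the itemized row-level errors in ``errors``.
    """

    def __init__(self, message: str, errors: list[str]):
        super().__init__(message)
        self.errors = errors
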