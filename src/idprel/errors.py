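"""Exception hierarchy for table ingestion and per-IDP analysis."""


class IdprelError(Exception):
    """Base class for all package errors."""


class FormatError(IdprelError):
    """Malformed input file (missing or misnamed columns, bad dialect)."""


class IntegrityError(IdprelError):
    """Table violates an invariant, e.g. duplicated (subject, session, idp) triple."""


class InsufficientDataError(IdprelError):
    """Too few complete-case subjects to analyse a phenotype.

    Carries the number of subjects that survived complete-case filtering.
    """

    def __init__(self, message: str, n_complete: int):
        super().__init__(message)
        self.n_complete = n_complete


class ConfigurationError(IdprelError):
    """A requested subset or configuration resolves to nothing analysable."""
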