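"""Exception hierarchy shared across the package."""


class OncomatchError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OncomatchError):
    """A record or file violates the declared schema or an invariant.

    Carries enough context (source, record index, field) to locate the
    offending entry in the input file.
    """

    def __init__(self, message, *, source=None, record=None, field=None):
        self.source = source
        self.record = record
        self.field = field
        parts = [message]
        if source is not None:
            parts.append(f"source={source!r}")
        if record is not None:
            parts.append(f"record={record!r}")
        if field is not None:
            parts.append(f"field={field!r}")
        super().__init__("; ".join(str(p) for p in parts))


class UnknownDrugError(OncomatchError, KeyError):
    """A drug id was looked up that does not exist in the knowledge base."""


class EmptyProfileError(OncomatchError):
    """Scoring was requested for a profile with no scoreable biomarkers.

    The matching score divides by the number of scoreable biomarkers, so it
    is undefined (not zero) for such profiles.
    """


class ConfigurationError(OncomatchError):
    """A scoring or ranking configuration references something unknown."""
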