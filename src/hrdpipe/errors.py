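"""Exception hierarchy shared across pipeline stages."""


class HrdPipeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HrdPipeError):
    """A configuration value is missing, malformed, or inconsistent."""


class DataError(HrdPipeError):
    """An input record violates its contract (bad coordinates, bad values)."""


class ReferenceMismatchError(DataError):
    """The stated reference allele disagrees with the reference sequence."""


class UnstableExtractionError(HrdPipeError):
    """De-novo extraction produced no component count with a quorum of votes.

    Carries the full vote table so the caller can inspect the restart
    behaviour before deciding how to proceed.
    """

    def __init__(self, message: str, votes: dict[int, int]):
        super().__init__(message)
        self.votes = dict(votes)
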