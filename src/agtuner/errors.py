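"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`AgtunerError`,
so callers (and the CLI) can separate data problems from genuine bugs.
"""


class AgtunerError(Exception):
    """Base class for all errors raised by agtuner."""


class MalformedInputError(AgtunerError):
    """A line of an input file (PAF, BED, blast tabular, TSV) could not be parsed."""


class MalformedProfileError(AgtunerError):
    """An HMMER3 text profile is truncated, inconsistent or not a profile at all."""


class InconsistentDatasetError(AgtunerError):
    """Orthogroup dataset files disagree (e.g. an id present in one cutoff table only)."""


class InvalidArgumentError(AgtunerError, ValueError):
    """An argument violates a documented precondition."""


class InvalidSplitError(InvalidArgumentError):
    """A dataset split would leave no testing partition."""


class UndefinedEntropyError(AgtunerError):
    """Relative entropy is undefined: an emission is positive where the background is zero."""


class NoSingleCopyGenesError(AgtunerError):
    """Cov(S) is undefined because no complete single-copy gene exists."""


class IncompleteCoverageError(AgtunerError):
    """A gene that AG must count has no coverage entry."""


class OptimizerError(AgtunerError):
    """The objective failed during the golden-section search.

    Carries ``partial_evaluations`` with the evaluations completed before the
    failure, so a long search is not lost entirely.
    """

    def __init__(self, message, partial_evaluations=None):
        super().__init__(message)
        self.partial_evaluations = list(partial_evaluations or [])


class BackendError(AgtunerError):
    """An assembler backend failed or is not runnable in this configuration."""
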