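"""Exception hierarchy shared across the package.

Every error raised on bad input derives from :class:`FaceTraitError`, so
callers can catch the package's failures without swallowing programming
errors.
"""


class FaceTraitError(Exception):
    """Base class for all errors raised by facetrait."""


class FormatError(FaceTraitError, ValueError):
    """A file or table does not match the declared interface."""


class ParseError(FormatError):
    """A value inside an otherwise well-formed file could not be parsed."""


class DegenerateDataError(FaceTraitError, ValueError):
    """Input data carry no information for the requested statistic."""


class DegenerateOrthogonalizationError(DegenerateDataError):
    """Target direction is (numerically) parallel to the nuisance direction."""


class UnderdeterminedFitError(FaceTraitError, ValueError):
    """Fewer observations than coefficients in a least-squares fit."""


class AlignmentError(FaceTraitError, ValueError):
    """Identifiers of two inputs that must match do not."""


class ContractError(FaceTraitError, ValueError):
    """An operation was called on an object in the wrong state."""


class MissingDataError(FaceTraitError, ValueError):
    """Missing entries where a complete table is required."""


class SpecificationError(FaceTraitError, ValueError):
    """A model specification is not identifiable on the given data."""


class ModelFitError(FaceTraitError, RuntimeError):
    """A candidate model failed to fit; carries the candidate's name."""

    def __init__(self, candidate: str, message: str):
        self.candidate = candidate
        super().__init__(f"candidate {candidate!r} failed: {message}")
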