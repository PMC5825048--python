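"""Exception hierarchy for swayblocks."""


class SwayBlocksError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SwayBlocksError, ValueError):
    """A file does not follow the expected on-disk format."""


class ValidationError(SwayBlocksError, ValueError):
    """Input data violates a structural invariant (e.g. non-monotone times)."""


class InsufficientDataError(SwayBlocksError, ValueError):
    """Too few samples/blocks/subjects for the requested operation."""


class DegenerateNormalizerError(SwayBlocksError, ValueError):
    """An index has zero variance across the training blocks."""


class StateError(SwayBlocksError, RuntimeError):
    """Operation requested on an object in the wrong state (e.g. unlabeled model)."""


class EvaluationError(SwayBlocksError, ValueError):
    """Evaluation protocol cannot proceed (single-class input, bad split, ...)."""
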