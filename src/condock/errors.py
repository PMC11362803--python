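"""Exception types shared across the package."""


class CondockError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CondockError):
    """An input violates a documented precondition or invariant."""


class ChainNotFoundError(ValidationError):
    """A requested chain id is absent from the structure file."""


class TopologyError(ValidationError):
    """Two structures expected to share an atom topology do not."""


class DegenerateGeometryError(ValidationError):
    """A point set is too degenerate (e.g. collinear) for superposition."""


class GenerationError(CondockError):
    """The synthetic ensemble generator produced an unusable ensemble."""
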