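"""Exception hierarchy for the pipeline."""


class ChickcallError(Exception):
    """Base class for all package errors."""


class FormatError(ChickcallError):
    """Unreadable or unsupported input file."""


class EmptyInputError(ChickcallError):
    """Input carries no usable samples/frames."""


class ParameterError(ChickcallError):
    """Invalid configuration value."""


class ShapeError(ChickcallError):
    """Array shape does not match the operation's contract."""


class BoundsError(ChickcallError):
    """Segment or index outside the addressable range."""


class DataError(ChickcallError):
    """Dataset construction or coverage problem."""


class TrainingError(ChickcallError):
    """Optimization failed (e.g. non-finite loss)."""


class InsufficientCallsError(ChickcallError):
    """A bird has fewer detected calls than the vote requires."""

    def __init__(self, chick_id, available, required):
        self.chick_id = chick_id
        self.available = available
        self.required = required
        super().__init__(
            f"chick {chick_id!r}: {available} calls available, "
            f"{required} required ({required - available} short)"
        )
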