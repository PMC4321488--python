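"""Exception hierarchy for detkit."""


class DetkitError(Exception):
    """Base class for all detkit errors."""


class InvalidCellError(DetkitError):
    """Unit-cell parameters do not describe a positive-volume lattice."""


class InvalidG6Error(DetkitError):
    """A G6 vector does not correspond to a valid unit cell."""


class ReductionError(DetkitError):
    """Niggli reduction failed to terminate (degenerate cell)."""


class SchemaError(DetkitError):
    """A frame file violates the det-frames-v1 schema."""

    def __init__(self, message, field=None, frame_index=None):
        self.field = field
        self.frame_index = frame_index
        parts = [message]
        if frame_index is not None:
            parts.append(f"(frame index {frame_index})")
        if field is not None:
            parts.append(f"[field: {field}]")
        super().__init__(" ".join(parts))


class StreamParseError(DetkitError):
    """A CrystFEL stream could not be parsed into any frame."""
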