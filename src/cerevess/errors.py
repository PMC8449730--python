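"""Shared exception types."""


class ValidationError(ValueError):
    """An input failed a precondition; the message names the field."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""
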