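"""Exception hierarchy shared across the pipeline."""


class SecircuitError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SecircuitError):
    """A file violated its format contract (bad coordinates, overlap, non-integer cell ...)."""


class UsageError(SecircuitError):
    """A function was called with arguments outside its contract."""
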