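"""Exception types shared across the pipeline."""


class NetmapError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(NetmapError, ValueError):
    """A function was called with parameters outside its contract."""


class FormatError(NetmapError, ValueError):
    """An input file violates its declared format; message carries the line number."""
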