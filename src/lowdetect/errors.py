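"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """An argument violates an operation's precondition."""


class FormatError(ValueError):
    """An input file does not parse as the expected format."""
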