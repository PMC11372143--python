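"""Exception hierarchy shared across the toolkit."""


class SeloopkitError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(SeloopkitError):
    """A simulation or pipeline configuration field is invalid.

    The message always names the offending field.
    """


class InputError(SeloopkitError):
    """An input table, interval, or file violates a documented precondition."""


class DegenerateInputError(InputError):
    """Input is syntactically valid but leaves the operation undefined
    (e.g. all stitched-enhancer signals equal, so no rank cutoff exists)."""
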