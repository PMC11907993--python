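"""Exception hierarchy shared across the package.

``InputError`` maps to CLI exit code 2 (bad user input), ``StageError``
to exit code 3 (a pipeline stage failed on otherwise valid input).
"""


class SmadscanError(Exception):
    """Base class for all package-specific errors."""


class InputError(SmadscanError, ValueError):
    """Invalid user input: malformed sequence, file, coordinate or parameter."""


class StageError(SmadscanError, RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""
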