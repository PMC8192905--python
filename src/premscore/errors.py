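"""Exception hierarchy.

``PremscoreError`` is the base for everything the package raises on purpose;
the CLI maps ``ConfigError`` (and subclasses) to exit code 1 and any other
failure to exit code 2.
"""


class PremscoreError(Exception):
    """Base class for all errors raised by premscore."""


class ConfigError(PremscoreError, ValueError):
    """Invalid configuration or invalid argument values."""


class FormatError(PremscoreError, ValueError):
    """A file could not be parsed, or metadata is missing/ambiguous."""


class DataError(PremscoreError, ValueError):
    """File parsed but its contents violate a data invariant."""


class AlignmentError(PremscoreError, ValueError):
    """Recording and hypnogram (or true/predicted label sequences) disagree in length."""
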