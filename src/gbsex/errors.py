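"""Exception hierarchy.

All anticipated user-facing failures derive from :class:`GbsexError` so the
CLI can map them to exit code 1; anything else is an internal error (exit 2).
"""


class GbsexError(Exception):
    """Base class for anticipated errors in gbsex."""


class FormatError(GbsexError):
    """A file does not conform to the expected format (VCF/TSV dialects)."""


class ConsistencyError(GbsexError):
    """Multiple inputs disagree (shape/ID mismatches, duplicated samples)."""


class ConfigError(GbsexError):
    """A configuration is invalid or a precondition on it is unmet."""


class InputError(GbsexError):
    """Input data violate an operation's precondition (e.g. empty SNP set)."""
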