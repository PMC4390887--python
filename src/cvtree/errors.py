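"""Exception hierarchy.

Exit codes (used by the CLI) distinguish usage errors, bad input files and
degenerate data, so batch callers can react differently to each.
"""


class CVTreeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class UsageError(CVTreeError):
    """Caller violated an API contract (mismatched K, bad matrix, ...)."""

    exit_code = 2


class InputError(CVTreeError):
    """A user-supplied file is missing, empty or malformed."""

    exit_code = 3


class ParseError(InputError):
    """Malformed content; message names the offending line where possible."""

    exit_code = 3


class DegenerateDataError(CVTreeError):
    """Structurally valid input that the method cannot operate on
    (e.g. a proteome with no countable K-peptide window)."""

    exit_code = 4
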