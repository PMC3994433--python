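"""Exception hierarchy.

Read failures are split into three layers so callers can report precisely why
an export is unusable: the file itself (``NotProcessable``), the XML syntax
(``MalformedXML``) or the dialect schema (``SchemaViolation``).
"""

from __future__ import annotations

__all__ = [
    "FlashdiffError",
    "NotProcessable",
    "MalformedXML",
    "SchemaViolation",
    "KBLoadError",
    "ChecklistContractError",
    "InvalidPattern",
    "UnresolvableTarget",
    "InapplicableCorruption",
]


class FlashdiffError(Exception):
    """Base class for all package errors."""


class NotProcessable(FlashdiffError):
    """Input file or stream is missing or unreadable."""


class MalformedXML(FlashdiffError):
    """Input is not well-formed XML."""


class SchemaViolation(FlashdiffError):
    """Well-formed XML that violates the flashdump dialect.

    ``path`` points at the offending element where known.
    """

    def __init__(self, message: str, path: str = ""):
        super().__init__(message if not path else f"{message} (at {path})")
        self.path = path


class KBLoadError(FlashdiffError):
    """Knowledge-base file rejected at load time.

    ``code`` is one of ``duplicate_dcu``, ``unknown_influence``,
    ``unknown_room``, ``empty_influences``, ``bad_format``; ``entry`` names
    the offending record where applicable.
    """

    def __init__(self, code: str, message: str, entry: str = ""):
        super().__init__(message)
        self.code = code
        self.entry = entry


class ChecklistContractError(FlashdiffError):
    """Checklist derivation requested although validation forbade it."""


class InvalidPattern(FlashdiffError):
    """Syntactically invalid output-filter pattern."""


class UnresolvableTarget(FlashdiffError):
    """A modification request addresses a non-existent dump location."""


class InapplicableCorruption(FlashdiffError):
    """Corruption mode incompatible with the supplied artifact arity."""
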