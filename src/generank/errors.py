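"""Exception hierarchy shared across the pipeline.

Every error raised on purpose by this package derives from
:class:`GeneRankError`, so callers (and the CLI) can distinguish expected
failure modes from genuine bugs.
"""

from __future__ import annotations


class GeneRankError(Exception):
    """Base class for all package errors."""


class ValidationError(GeneRankError):
    """Input violates a structural contract (bad symbol, bad config value)."""


class GmtFormatError(ValidationError):
    """A GMT line is malformed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class ModuleLookupError(GeneRankError, KeyError):
    """Unknown module id; message lists the available ids."""


class ParseError(GeneRankError):
    """A structured text artifact (score record, sentence) failed to parse."""


class MissingFixtureError(GeneRankError, KeyError):
    """A scripted backend has no canned response for the request."""


class ContextOverflowError(GeneRankError):
    """A prompt exceeds the backend's declared context budget."""


class DuplicateCellError(GeneRankError):
    """Two conflicting score records target the same tensor cell."""


class ExtractionError(GeneRankError):
    """A selection response names no (or no unambiguous) candidate gene."""


class ConfigError(ValidationError):
    """Workflow or generator configuration is invalid."""


class CorruptFixtureError(GeneRankError):
    """A packaged resource does not match its recorded checksum."""


class BackendError(GeneRankError):
    """A backend failed after exhausting its retry budget."""


class TransientBackendError(BackendError):
    """A transport-level failure that is worth retrying."""
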