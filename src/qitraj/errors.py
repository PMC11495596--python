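"""Exception types shared across the pipeline stages."""

from __future__ import annotations


class QitrajError(Exception):
    """Base class for all package errors."""


class DomainError(QitrajError, ValueError):
    """An argument is outside the mathematical domain of a formula."""


class ConfigurationError(QitrajError, ValueError):
    """A configuration value is structurally invalid for the requested operation."""


class MissingCellsError(QitrajError):
    """The panel is not rectangular: some (area, period) cells are absent.

    Attributes
    ----------
    cells : list of (area_id, period) tuples that are missing.
    """

    def __init__(self, cells):
        self.cells = list(cells)
        preview = ", ".join(f"({a}, {p})" for a, p in self.cells[:10])
        more = "" if len(self.cells) <= 10 else f" … ({len(self.cells)} total)"
        super().__init__(f"missing (area, period) cells: {preview}{more}")


class UnmatchedAreasError(QitrajError):
    """Assigned areas lack covariate rows (or vice versa)."""

    def __init__(self, area_ids):
        self.area_ids = list(area_ids)
        preview = ", ".join(map(str, self.area_ids[:10]))
        more = "" if len(self.area_ids) <= 10 else f" … ({len(self.area_ids)} total)"
        super().__init__(f"area ids without covariate rows: {preview}{more}")


class ConvergenceError(QitrajError):
    """EM failed to produce a usable fit after exhausting all restarts."""

    def __init__(self, message, best_attempt=None):
        self.best_attempt = best_attempt
        super().__init__(message)


class PipelineError(QitrajError):
    """A pipeline stage failed; carries the stage name and the structured cause."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
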