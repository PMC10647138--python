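"""Exception hierarchy for the whtr_cutoffs package."""

from __future__ import annotations


class WhtrError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(WhtrError):
    """A column mapping or configuration problem (missing column, bad unit)."""


class CohortValidationError(WhtrError):
    """One or more rows violated the participant-record invariants.

    Carries row-indexed diagnostics so callers can report or fix inputs.
    """

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.diagnostics[:20])
        extra = "" if len(self.diagnostics) <= 20 else f" (+{len(self.diagnostics) - 20} more)"
        super().__init__(f"{len(self.diagnostics)} invalid row(s): {lines}{extra}")


class ReferenceValidationError(WhtrError):
    """A reference table violates its structural invariants."""


class ReferenceCoverageError(WhtrError):
    """A lookup falls outside the age (or other) coverage of a reference table."""


class EmptySubsampleError(WhtrError):
    """A weight-status subsample contains no records."""


class SparseCellError(WhtrError):
    """Percentile-table cells below the minimum per-cell sample size."""

    def __init__(self, cells, min_n):
        self.cells = list(cells)
        self.min_n = min_n
        super().__init__(
            f"{len(self.cells)} (sex, age) cell(s) below minimum n={min_n}: "
            + ", ".join(f"({s}, {a}) n={n}" for s, a, n in self.cells)
        )


class MissingCellError(WhtrError):
    """A (sex, age) cell required for a lookup is absent from a percentile table."""


class DegenerateOutcomeError(WhtrError):
    """The outcome (or exposure) has no positives or no negatives; ROC/OR undefined."""


class SeparationError(WhtrError):
    """Logistic-regression design exhibits (quasi-)complete separation."""


class RankDeficientError(WhtrError):
    """Logistic-regression design matrix is rank deficient."""


class CalibrationError(WhtrError):
    """A synthetic-cohort configuration cannot reach its stated prevalence target."""
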