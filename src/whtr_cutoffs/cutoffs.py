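"""Candidate WHtR cut-offs as binary classifiers for risk clustering.

A single dichotomising cut-off c classifies a child as positive when
WHtR >= c (the boundary is positive).  Against the binary clustering
outcome this yields one (sensitivity, specificity) operating point, for
which

    AUC    = (sensitivity + specificity) / 2
    Youden = sensitivity + specificity - 1 = 2 * AUC - 1

so maximising the Youden index and maximising AUC select the same
candidate.  Two candidate families are searched:

* *percentile candidates* -- the child's own sex/age-specific WHtR
  percentile (P75..P95 by default) estimated on the reference subsample;
* a *static grid* -- fixed WHtR values 0.42, 0.43, ..., 0.56.

The 95% CI for the single-cut-off AUC combines the two binomial variances:
AUC +/- 1.96 * sqrt(se(1-se)/(4*n_pos) + sp(1-sp)/(4*n_neg)), clipped to
[0, 1]; sensitivity and specificity get Wald CIs on their own denominators.
Per-stratum optimal static cut-offs are consolidated to one proposed value
per region group as the group median, rounded half-up to two decimals.
"""

from __future__ import annotations

import dataclasses
import logging
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .criteria import Criteria, clustering_mask, flag_frame
from .errors import DegenerateOutcomeError, WhtrError
from .references import BPReferenceTable
from .subsamples import DEFAULT_CANDIDATES, PercentileTable, exceeds_percentile

logger = logging.getLogger(__name__)

GRID_LO = 0.42
GRID_HI = 0.56
GRID_STEP = 0.01


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise WhtrError("confusion counts must be non-negative")
        if self.positives == 0 or self.negatives == 0:
            raise DegenerateOutcomeError(
                f"outcome degenerate: {self.positives} positive(s), {self.negatives} negative(s)"
            )

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclasses.dataclass(frozen=True)
class CutoffEvaluation:
    """Classifier metrics for one candidate cut-off.

    ``cutoff`` is a static WHtR value (kind="static") or a percentile label
    (kind="percentile").
    """

    cutoff: float | int
    kind: str
    sens: float
    spec: float
    auc: float
    auc_ci: tuple[float, float]
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    youden: float
    counts: ConfusionCounts
    criteria: Criteria | None = None
    k: int | None = None

    @property
    def n(self) -> int:
        return self.counts.n


def _as_mask(cohort: Cohort, fn_or_mask) -> np.ndarray:
    if callable(fn_or_mask):
        return np.fromiter((bool(fn_or_mask(r)) for r in cohort.records()), dtype=bool, count=len(cohort))
    return np.asarray(fn_or_mask, dtype=bool)


def confusion_at(cohort: Cohort, classifier, outcome) -> ConfusionCounts:
    """Exhaustive 2x2 tally of a classifier against the outcome.

    ``classifier`` and ``outcome`` may be boolean arrays aligned with the
    cohort or callables mapping a record to bool.
    """
    c = _as_mask(cohort, classifier)
    y = _as_mask(cohort, outcome)
    if c.shape != y.shape or c.shape[0] != len(cohort):
        raise WhtrError("classifier/outcome masks must align with the cohort")
    tp = int(np.sum(c & y))
    fp = int(np.sum(c & ~y))
    fn = int(np.sum(~c & y))
    tn = int(np.sum(~c & ~y))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _wald(p: float, n: int) -> tuple[float, float]:
    half = 1.96 * np.sqrt(p * (1.0 - p) / n)
    return (float(max(0.0, p - half)), float(min(1.0, p + half)))


def evaluate_cutoff(
    counts: ConfusionCounts,
    cutoff: float | int = float("nan"),
    kind: str = "static",
    criteria: Criteria | None = None,
    k: int | None = None,
) -> CutoffEvaluation:
    """Sensitivity, specificity, AUC (+CI) and Youden index from a 2x2 tally."""
    sens = counts.tp / counts.positives
    spec = counts.tn / counts.negatives
    auc = (sens + spec) / 2.0
    youden = sens + spec - 1.0
    half = 1.96 * np.sqrt(
        sens * (1.0 - sens) / (4.0 * counts.positives)
        + spec * (1.0 - spec) / (4.0 * counts.negatives)
    )
    auc_ci = (float(max(0.0, auc - half)), float(min(1.0, auc + half)))
    return CutoffEvaluation(
        cutoff=cutoff,
        kind=kind,
        sens=float(sens),
        spec=float(spec),
        auc=float(auc),
        auc_ci=auc_ci,
        sens_ci=_wald(sens, counts.positives),
        spec_ci=_wald(spec, counts.negatives),
        youden=float(youden),
        counts=counts,
        criteria=criteria,
        k=k,
    )


def outcome_mask(
    cohort: Cohort, criteria: Criteria, k: int = 2, bp_ref: BPReferenceTable | None = None
) -> np.ndarray:
    """Clustering indicator (>= k of 4 components) per record."""
    return clustering_mask(flag_frame(cohort, criteria, bp_ref), k)


def evaluate_percentile_candidates(
    cohort: Cohort,
    table: PercentileTable,
    candidates: Sequence[int] = DEFAULT_CANDIDATES,
    criteria: Criteria = Criteria.IDF,
    k: int = 2,
    bp_ref: BPReferenceTable | None = None,
    outcome: np.ndarray | None = None,
) -> list[CutoffEvaluation]:
    """One evaluation per percentile candidate, on the full cohort.

    The classifier for candidate p is "WHtR >= own (sex, age) cell's Pp";
    the percentile table comes from the reference subsample but candidates
    are always judged on the full cohort.
    """
    y = outcome if outcome is not None else outcome_mask(cohort, criteria, k, bp_ref)
    evals = []
    for p in candidates:
        mask = exceeds_percentile(cohort, table, p)
        counts = confusion_at(cohort, mask, y)
        evals.append(evaluate_cutoff(counts, cutoff=int(p), kind="percentile", criteria=criteria, k=k))
    return evals


def static_grid(lo: float = GRID_LO, hi: float = GRID_HI, step: float = GRID_STEP) -> list[float]:
    """Grid values computed in integer hundredths so there is no float drift."""
    lo_i, hi_i, step_i = round(lo * 100), round(hi * 100), round(step * 100)
    if lo_i >= hi_i or step_i <= 0:
        raise WhtrError("grid requires lo < hi and step > 0")
    return [i / 100.0 for i in range(lo_i, hi_i + 1, step_i)]


def evaluate_static_grid(
    cohort: Cohort,
    criteria: Criteria = Criteria.IDF,
    k: int = 2,
    bp_ref: BPReferenceTable | None = None,
    lo: float = GRID_LO,
    hi: float = GRID_HI,
    step: float = GRID_STEP,
    outcome: np.ndarray | None = None,
) -> list[CutoffEvaluation]:
    """One evaluation per static grid value; classifier is WHtR >= cutoff."""
    y = outcome if outcome is not None else outcome_mask(cohort, criteria, k, bp_ref)
    whtr = cohort.df["whtr"].to_numpy(dtype=float)
    evals = []
    for c in static_grid(lo, hi, step):
        counts = confusion_at(cohort, whtr >= c, y)
        evals.append(evaluate_cutoff(counts, cutoff=c, kind="static", criteria=criteria, k=k))
    return evals


def select_optimal(evals: Sequence[CutoffEvaluation], log: list[str] | None = None) -> CutoffEvaluation:
    """Evaluation maximising the Youden index (equivalently AUC).

    Exact ties break toward higher sensitivity, then the lower cut-off; the
    tie-break path is logged.
    """
    if not evals:
        raise WhtrError("cannot select an optimum from an empty evaluation list")
    best = max(evals, key=lambda e: (e.youden, e.sens, -float(e.cutoff)))
    tied = [e for e in evals if e.youden == best.youden]
    if len(tied) > 1:
        msg = (
            f"Youden tie among cutoffs {[e.cutoff for e in tied]}; "
            f"resolved to {best.cutoff} (higher sensitivity, then lower cutoff)"
        )
        logger.info(msg)
        if log is not None:
            log.append(msg)
    return best


@dataclasses.dataclass(frozen=True)
class ProposedCutoffs:
    """One proposed static WHtR cut-off per region group, with dispersion."""

    values: dict[str, float]
    dispersion: pd.DataFrame

    def __post_init__(self):
        for group, v in self.values.items():
            if not (0.40 <= v <= 0.60):
                raise WhtrError(f"proposed cutoff for group {group!r} outside [0.40, 0.60]: {v}")


def _round_half_up_2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def consolidate(
    optima: Mapping[str, float], grouping: Mapping[str, str]
) -> ProposedCutoffs:
    """Group per-stratum optimal static cut-offs into proposed values.

    Each stratum's optimum is assigned to its region group; the proposal is
    the group median rounded half-up to two decimals, reported alongside
    min/max/IQR so the clustering tendency of the member optima is
    inspectable.
    """
    missing = [s for s in optima if s not in grouping]
    if missing:
        raise WhtrError(f"strata without a group assignment: {missing}")
    members: dict[str, list[float]] = {}
    for stratum, value in optima.items():
        members.setdefault(grouping[stratum], []).append(float(value))
    if not members:
        raise WhtrError("no strata to consolidate")
    values = {}
    rows = []
    for group, vals in sorted(members.items()):
        arr = np.sort(np.asarray(vals, dtype=float))
        proposed = _round_half_up_2(np.median(arr))
        values[group] = proposed
        q1, q3 = np.quantile(arr, [0.25, 0.75])
        rows.append(
            {
                "group": group,
                "proposed": proposed,
                "n_strata": len(arr),
                "min": float(arr[0]),
                "max": float(arr[-1]),
                "iqr": float(q3 - q1),
            }
        )
    return ProposedCutoffs(values=values, dispersion=pd.DataFrame(rows))


def evaluations_to_frame(evals: Sequence[CutoffEvaluation], stratum: str = "") -> pd.DataFrame:
    """Results rows (stratum, criteria, cutoff, AUC/CI, sens, spec, Youden, n)."""
    rows = []
    for e in evals:
        rows.append(
            {
                "stratum": stratum,
                "criteria": e.criteria.value if e.criteria else "",
                "k": e.k,
                "kind": e.kind,
                "cutoff": e.cutoff,
                "auc": e.auc,
                "auc_lo": e.auc_ci[0],
                "auc_hi": e.auc_ci[1],
                "sens": e.sens,
                "spec": e.spec,
                "youden": e.youden,
                "n": e.n,
            }
        )
    return pd.DataFrame(rows)
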