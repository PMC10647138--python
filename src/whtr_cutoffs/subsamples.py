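"""Weight-status subsamples and WHtR percentile reference tables.

Extreme weight statuses distort weight-related reference distributions, so
percentile reference values are estimated on a restricted subsample.  Six
candidate subsamples are defined by which weight-status categories they admit:

====  =====================================================
S1    entire population
S2    normal weight only
S3    normal weight + thinness grade 1 + overweight
S4    normal weight + overweight + obesity
S5    normal weight + overweight
S6    normal weight + overweight + obesity + morbid obesity
====  =====================================================

The *reference subsample* is the one with the lowest prevalence of
cardiometabolic risk-factor clustering (ties resolved toward the smaller
membership set, so S2 wins exact ties).  Sex- and age-specific WHtR
percentiles are then estimated on it; candidate cut-offs are evaluated on
the full cohort, not the reference subsample.

Quantile convention: linear interpolation between the closest order
statistics (numpy's ``method="linear"``), fixed package-wide and
configurable per call for sensitivity checks.
"""

from __future__ import annotations

import dataclasses
import enum
import logging

import numpy as np
import pandas as pd

from .cohort import Cohort, ParticipantRecord
from .criteria import Criteria, clustering_proportion
from .errors import EmptySubsampleError, MissingCellError, SparseCellError
from .references import BPReferenceTable, GrowthReferenceTable, WeightStatus

logger = logging.getLogger(__name__)

DEFAULT_CANDIDATES = (75, 80, 85, 90, 95)
DEFAULT_MIN_CELL_N = 10
QUANTILE_METHOD = "linear"


class SubsampleId(enum.Enum):
    S1 = "S1"
    S2 = "S2"
    S3 = "S3"
    S4 = "S4"
    S5 = "S5"
    S6 = "S6"


MEMBERSHIP: dict[SubsampleId, frozenset[WeightStatus]] = {
    SubsampleId.S1: frozenset(WeightStatus),
    SubsampleId.S2: frozenset({WeightStatus.NORMAL}),
    SubsampleId.S3: frozenset({WeightStatus.NORMAL, WeightStatus.THIN1, WeightStatus.OVERWEIGHT}),
    SubsampleId.S4: frozenset({WeightStatus.NORMAL, WeightStatus.OVERWEIGHT, WeightStatus.OBESE}),
    SubsampleId.S5: frozenset({WeightStatus.NORMAL, WeightStatus.OVERWEIGHT}),
    SubsampleId.S6: frozenset(
        {WeightStatus.NORMAL, WeightStatus.OVERWEIGHT, WeightStatus.OBESE, WeightStatus.MORBID_OBESE}
    ),
}

#: Tie-break order for the reference-subsample argmin: smaller membership
#: set first (S2 before S5 before S3/S4 before S6 before S1).
TIE_ORDER = (
    SubsampleId.S2,
    SubsampleId.S5,
    SubsampleId.S3,
    SubsampleId.S4,
    SubsampleId.S6,
    SubsampleId.S1,
)


def weight_status_series(cohort: Cohort, growth_ref: GrowthReferenceTable) -> np.ndarray:
    """Per-record weight status (as WeightStatus int codes)."""
    return growth_ref.classify_frame(cohort.df)


def build_subsample(
    cohort: Cohort, subsample: SubsampleId, growth_ref: GrowthReferenceTable
) -> Cohort:
    """Records whose weight status belongs to the subsample's membership set."""
    status = weight_status_series(cohort, growth_ref)
    allowed = np.array([int(s) for s in MEMBERSHIP[subsample]])
    mask = np.isin(status, allowed)
    return cohort.subset(mask, label=f"{cohort.label}:{subsample.value}")


def subsample_proportions(
    cohort: Cohort,
    criteria: Criteria,
    k: int = 2,
    bp_ref: BPReferenceTable | None = None,
    growth_ref: GrowthReferenceTable | None = None,
) -> pd.DataFrame:
    """Clustering prevalence in each of the six subsamples (reporting table)."""
    rows = []
    for sid in SubsampleId:
        sub = build_subsample(cohort, sid, growth_ref)
        if len(sub) == 0:
            raise EmptySubsampleError(f"subsample {sid.value} of cohort {cohort.label!r} is empty")
        prop = clustering_proportion(sub, criteria, k, bp_ref)
        rows.append(
            {
                "subsample": sid.value,
                "n": prop.denominator,
                "clustered": prop.numerator,
                "proportion": prop.fraction,
            }
        )
    return pd.DataFrame(rows)


def select_reference_subsample(
    cohort: Cohort,
    criteria: Criteria,
    k: int = 2,
    bp_ref: BPReferenceTable | None = None,
    growth_ref: GrowthReferenceTable | None = None,
) -> tuple[SubsampleId, pd.DataFrame]:
    """Subsample with minimal clustering prevalence, plus the full table.

    Exact ties go to the smaller membership set (S2 first).
    """
    table = subsample_proportions(cohort, criteria, k, bp_ref, growth_ref)
    props = dict(zip(table["subsample"], table["proportion"]))
    best = min(TIE_ORDER, key=lambda sid: (props[sid.value], TIE_ORDER.index(sid)))
    return best, table


@dataclasses.dataclass(frozen=True)
class PercentileTable:
    """Sex x age grid of WHtR percentile values with per-cell sample sizes.

    Long-format frame with columns sex, age, p, value, n; ``values`` gives
    O(1) cell lookup.
    """

    df: pd.DataFrame
    candidates: tuple[int, ...]

    @property
    def values(self) -> dict:
        return self._index()

    def _index(self) -> dict:
        if not hasattr(self, "_cache"):
            object.__setattr__(
                self,
                "_cache",
                {
                    (r.sex, int(r.age), int(r.p)): float(r.value)
                    for r in self.df.itertuples(index=False)
                },
            )
        return self._cache

    def lookup(self, sex: str, age: int, p: int) -> float:
        key = (sex, int(age), int(p))
        idx = self._index()
        if key not in idx:
            raise MissingCellError(f"no percentile cell for (sex={sex}, age={age}, p={p})")
        return idx[key]

    def thresholds_for(self, df: pd.DataFrame, p: int) -> np.ndarray:
        """Per-record WHtR threshold at percentile ``p`` for a cohort frame."""
        idx = self._index()
        out = np.empty(len(df), dtype=float)
        sexes = df["sex"].to_numpy()
        ages = df["age_years"].to_numpy()
        for i in range(len(df)):
            key = (sexes[i], int(ages[i]), int(p))
            if key not in idx:
                raise MissingCellError(
                    f"no percentile cell for (sex={sexes[i]}, age={ages[i]}, p={p})"
                )
            out[i] = idx[key]
        return out

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def whtr_percentile_table(
    reference: Cohort,
    candidates=DEFAULT_CANDIDATES,
    min_cell_n: int = DEFAULT_MIN_CELL_N,
    method: str = QUANTILE_METHOD,
) -> PercentileTable:
    """Empirical WHtR percentiles per (sex, age) cell of the reference cohort.

    Cells below ``min_cell_n`` raise :class:`SparseCellError` (no silent
    pooling of adjacent ages).
    """
    candidates = tuple(sorted(int(p) for p in candidates))
    groups = reference.df.groupby(["sex", "age_years"], sort=True)
    sparse = [
        (sex, int(age), len(grp))
        for (sex, age), grp in groups
        if len(grp) < min_cell_n
    ]
    if sparse:
        raise SparseCellError(sparse, min_cell_n)
    rows = []
    for (sex, age), grp in groups:
        values = np.quantile(
            grp["whtr"].to_numpy(dtype=float), [p / 100.0 for p in candidates], method=method
        )
        for p, v in zip(candidates, values):
            rows.append({"sex": sex, "age": int(age), "p": p, "value": float(v), "n": len(grp)})
    return PercentileTable(pd.DataFrame(rows), candidates)


def exceeds_percentile(obj, table: PercentileTable, p: int):
    """True iff WHtR >= the (sex, age)-specific percentile value (>= at boundary).

    Accepts a single :class:`ParticipantRecord` (returns bool) or a
    :class:`Cohort` (returns a boolean array).
    """
    if isinstance(obj, ParticipantRecord):
        return bool(obj.derived.whtr >= table.lookup(obj.sex, obj.age_years, p))
    df = obj.df if isinstance(obj, Cohort) else obj
    thresholds = table.thresholds_for(df, p)
    return df["whtr"].to_numpy(dtype=float) >= thresholds
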