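"""Cardiometabolic component risk factors and their clustering.

Four metabolic-syndrome components are flagged per child (the waist
component is deliberately excluded because it is collinear with WHtR):

==============  ==========================  ===============================
component       IDF rule                    NCEP (modified) rule
==============  ==========================  ===============================
high TG         TG >= 150 mg/dL             TG >= 110 mg/dL
low HDL-C       HDL < 40 (ages 6-15);       HDL <= 40 mg/dL (note <=)
                boys >= 16: HDL < 40;
                girls >= 16: HDL < 50
high BP         SBP/DBP >= 120/80 (6-9 y)   SBP/DBP >= sex/age/height 90th
                SBP/DBP >= 130/85 (>=10 y)  percentile (6-17 y);
                                            >= 130/85 at age 18
high FBG        FBG >= 100 mg/dL            FBG >= 110 mg/dL
==============  ==========================  ===============================

"SBP/DBP >= X/Y" means SBP >= X *or* DBP >= Y.  All comparisons use the
printed inequality exactly (NCEP's ``<=`` for HDL versus IDF's ``<``).

*Clustering* is the presence of at least k of the four components (k = 2 in
the main analysis, k = 3 in sensitivity analyses).
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
import pandas as pd

from .cohort import Cohort, FEMALE, MALE, ParticipantRecord
from .errors import DegenerateOutcomeError, WhtrError
from .references import BPReferenceTable

FLAG_COLUMNS = ("high_bp", "high_tg", "low_hdl", "high_fbg")


class Criteria(str, enum.Enum):
    """Which published pediatric MetS component definitions to apply."""

    IDF = "IDF"
    NCEP = "NCEP"


@dataclasses.dataclass(frozen=True)
class ComponentFlags:
    """The four component booleans for one record under a named criteria set."""

    high_bp: bool
    high_tg: bool
    low_hdl: bool
    high_fbg: bool
    criteria: Criteria

    @property
    def count(self) -> int:
        return int(self.high_bp) + int(self.high_tg) + int(self.low_hdl) + int(self.high_fbg)


def idf_flag_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised IDF component flags for a cohort frame."""
    age = df["age_years"].to_numpy()
    male = (df["sex"] == MALE).to_numpy()
    tg = df["tg_mgdl"].to_numpy(dtype=float)
    hdl = df["hdl_mgdl"].to_numpy(dtype=float)
    sbp = df["sbp_mmHg"].to_numpy(dtype=float)
    dbp = df["dbp_mmHg"].to_numpy(dtype=float)
    fbg = df["fbg_mgdl"].to_numpy(dtype=float)

    high_tg = tg >= 150.0
    low_hdl = np.where(age <= 15, hdl < 40.0, np.where(male, hdl < 40.0, hdl < 50.0))
    high_bp = np.where(age <= 9, (sbp >= 120.0) | (dbp >= 80.0), (sbp >= 130.0) | (dbp >= 85.0))
    high_fbg = fbg >= 100.0
    out = pd.DataFrame(
        {"high_bp": high_bp, "high_tg": high_tg, "low_hdl": low_hdl, "high_fbg": high_fbg}
    )
    out["count"] = out[list(FLAG_COLUMNS)].sum(axis=1)
    return out


def ncep_flag_frame(df: pd.DataFrame, bp_ref: BPReferenceTable) -> pd.DataFrame:
    """Vectorised modified-NCEP component flags; needs the child BP reference."""
    age = df["age_years"].to_numpy()
    tg = df["tg_mgdl"].to_numpy(dtype=float)
    hdl = df["hdl_mgdl"].to_numpy(dtype=float)
    sbp = df["sbp_mmHg"].to_numpy(dtype=float)
    dbp = df["dbp_mmHg"].to_numpy(dtype=float)
    fbg = df["fbg_mgdl"].to_numpy(dtype=float)

    high_bp = np.empty(len(df), dtype=bool)
    adult = age >= 18
    high_bp[adult] = (sbp[adult] >= 130.0) | (dbp[adult] >= 85.0)
    child = ~adult
    if child.any():
        sub = df.loc[child].reset_index(drop=True)
        sbp90, dbp90 = bp_ref.lookup_frame(sub)
        high_bp[child] = (sbp[child] >= sbp90) | (dbp[child] >= dbp90)

    out = pd.DataFrame(
        {
            "high_bp": high_bp,
            "high_tg": tg >= 110.0,
            "low_hdl": hdl <= 40.0,
            "high_fbg": fbg >= 110.0,
        }
    )
    out["count"] = out[list(FLAG_COLUMNS)].sum(axis=1)
    return out


def flag_frame(
    cohort: Cohort | pd.DataFrame, criteria: Criteria, bp_ref: BPReferenceTable | None = None
) -> pd.DataFrame:
    """Component flags plus count for every record of a cohort."""
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    criteria = Criteria(criteria)
    if criteria is Criteria.IDF:
        return idf_flag_frame(df)
    if bp_ref is None:
        raise WhtrError("NCEP criteria require a BP reference table")
    return ncep_flag_frame(df, bp_ref)


def _single(record: ParticipantRecord) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(record)])


def flag_idf(record: ParticipantRecord) -> ComponentFlags:
    """IDF component flags for a single record."""
    row = idf_flag_frame(_single(record)).iloc[0]
    return ComponentFlags(
        bool(row.high_bp), bool(row.high_tg), bool(row.low_hdl), bool(row.high_fbg), Criteria.IDF
    )


def flag_ncep(record: ParticipantRecord, bp_ref: BPReferenceTable) -> ComponentFlags:
    """Modified-NCEP component flags for a single record."""
    row = ncep_flag_frame(_single(record), bp_ref).iloc[0]
    return ComponentFlags(
        bool(row.high_bp), bool(row.high_tg), bool(row.low_hdl), bool(row.high_fbg), Criteria.NCEP
    )


def clustering(flags: ComponentFlags, k: int = 2) -> bool:
    """True iff at least ``k`` of the four component flags are set (k in {2, 3, 4})."""
    if k not in (2, 3, 4):
        raise WhtrError(f"k must be one of 2, 3, 4; got {k}")
    return flags.count >= k


def clustering_mask(flag_table: pd.DataFrame, k: int = 2) -> np.ndarray:
    """Boolean clustering indicator per record from a flag frame."""
    if k not in (2, 3, 4):
        raise WhtrError(f"k must be one of 2, 3, 4; got {k}")
    return (flag_table["count"].to_numpy() >= k)


@dataclasses.dataclass(frozen=True)
class ClusteringProportion:
    fraction: float
    numerator: int
    denominator: int


def clustering_proportion(
    cohort: Cohort,
    criteria: Criteria,
    k: int = 2,
    bp_ref: BPReferenceTable | None = None,
) -> ClusteringProportion:
    """Fraction of a cohort with >= k component risk factors."""
    if len(cohort) == 0:
        raise DegenerateOutcomeError("clustering proportion of an empty cohort is undefined")
    mask = clustering_mask(flag_frame(cohort, criteria, bp_ref), k)
    return ClusteringProportion(float(mask.mean()), int(mask.sum()), int(mask.size))
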