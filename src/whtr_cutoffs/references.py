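"""Pluggable anthropometric reference tables.

Two references are needed:

* a growth reference of sex- and age-specific BMI boundaries (IOTF-style
  cut-offs for thinness grades 3/2/1, overweight, obesity and morbid
  obesity) used to classify weight status, and
* a child blood-pressure reference giving the sex-, age- and height-specific
  90th percentiles of SBP/DBP used by the NCEP high-BP rule.

Both are plain CSV data files so the published tables can be dropped in;
the bundled synthetic tables (see :mod:`whtr_cutoffs.synthetic`) have the
same shape and are what the test-suite runs against.

Conventions (fixed here because the sources leave them open):

* A BMI exactly on a boundary belongs to the heavier category.
* Boundaries between tabulated ages are linearly interpolated.
* The BP reference is keyed by discrete half-open height bands
  ``[height_low, height_high)``; heights outside all bands clamp to the
  nearest band with a logged warning.
"""

from __future__ import annotations

import enum
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import FEMALE, MALE
from .errors import ReferenceCoverageError, ReferenceValidationError

logger = logging.getLogger(__name__)

BOUNDARY_COLUMNS = ("thin3", "thin2", "thin1", "overweight", "obesity", "morbid_obesity")


class WeightStatus(enum.IntEnum):
    """Weight-status categories, totally ordered light to heavy."""

    THIN3 = 0
    THIN2 = 1
    THIN1 = 2
    NORMAL = 3
    OVERWEIGHT = 4
    OBESE = 5
    MORBID_OBESE = 6


class GrowthReferenceTable:
    """Sex/age grid of the six BMI category boundaries.

    ``thin3`` is the upper edge of thinness grade 3 (so BMI below it is
    THIN3), ``overweight`` the lower edge of overweight, and so on; at every
    grid point the six values must strictly increase.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"sex", "age", *BOUNDARY_COLUMNS}
        missing = required - set(df.columns)
        if missing:
            raise ReferenceValidationError(f"growth reference missing columns: {sorted(missing)}")
        df = df.sort_values(["sex", "age"]).reset_index(drop=True)
        for _, row in df.iterrows():
            vals = [row[c] for c in BOUNDARY_COLUMNS]
            if not all(b > a for a, b in zip(vals, vals[1:])):
                raise ReferenceValidationError(
                    f"boundaries not strictly increasing at (sex={row['sex']}, age={row['age']}): {vals}"
                )
        for sex, grp in df.groupby("sex"):
            if grp["age"].min() > 6 or grp["age"].max() < 18:
                raise ReferenceValidationError(
                    f"growth reference for sex={sex} must cover ages [6, 18]; "
                    f"got [{grp['age'].min()}, {grp['age'].max()}]"
                )
        self.df = df
        self._by_sex = {
            sex: (grp["age"].to_numpy(dtype=float),
                  {c: grp[c].to_numpy(dtype=float) for c in BOUNDARY_COLUMNS})
            for sex, grp in df.groupby("sex")
        }

    def boundaries_at(self, sex: str, age) -> np.ndarray:
        """Linearly interpolated boundaries at ``age`` (scalar or array); shape (..., 6)."""
        if sex not in self._by_sex:
            raise ReferenceCoverageError(f"no growth reference for sex={sex!r}")
        ages, cols = self._by_sex[sex]
        age = np.asarray(age, dtype=float)
        if np.any(age < ages.min()) or np.any(age > ages.max()):
            raise ReferenceCoverageError(
                f"age outside growth-reference coverage [{ages.min()}, {ages.max()}]"
            )
        return np.stack([np.interp(age, ages, cols[c]) for c in BOUNDARY_COLUMNS], axis=-1)

    def classify(self, sex: str, age, bmi):
        """Weight status for scalar inputs (see :func:`classify_weight_status`)."""
        bounds = self.boundaries_at(sex, age)
        return WeightStatus(int(np.sum(np.asarray(bmi) >= bounds)))

    def classify_frame(self, df: pd.DataFrame) -> np.ndarray:
        """Vectorised weight status for a cohort frame with sex/age_years/bmi."""
        out = np.empty(len(df), dtype=np.int64)
        for sex in (MALE, FEMALE):
            mask = (df["sex"] == sex).to_numpy()
            if not mask.any():
                continue
            bounds = self.boundaries_at(sex, df.loc[mask, "age_years"].to_numpy(dtype=float))
            bmi = df.loc[mask, "bmi"].to_numpy(dtype=float)
            out[mask] = np.sum(bmi[:, None] >= bounds, axis=1)
        return out


class BPReferenceTable:
    """Sex/age/height-band table of SBP and DBP 90th percentiles (mmHg).

    Bands are half-open ``[height_low, height_high)``; covers ages 6-17.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"sex", "age", "height_low", "height_high", "sbp90", "dbp90"}
        missing = required - set(df.columns)
        if missing:
            raise ReferenceValidationError(f"BP reference missing columns: {sorted(missing)}")
        if (df[["sbp90", "dbp90"]] <= 0).any().any():
            raise ReferenceValidationError("BP thresholds must be strictly positive")
        if (df["sbp90"] <= df["dbp90"]).any():
            raise ReferenceValidationError("sbp90 must exceed dbp90 in every cell")
        for sex in (MALE, FEMALE):
            ages = set(df.loc[df["sex"] == sex, "age"].astype(int))
            if not set(range(6, 18)) <= ages:
                raise ReferenceValidationError(
                    f"BP reference for sex={sex} must cover ages 6-17; has {sorted(ages)}"
                )
        self.df = df.sort_values(["sex", "age", "height_low"]).reset_index(drop=True)
        self._cells = {}
        for (sex, age), grp in self.df.groupby(["sex", "age"]):
            lows = grp["height_low"].to_numpy(dtype=float)
            if np.any(np.diff(lows) <= 0):
                raise ReferenceValidationError(f"overlapping height bands at ({sex}, {age})")
            self._cells[(sex, int(age))] = (
                lows,
                grp["height_high"].to_numpy(dtype=float),
                grp["sbp90"].to_numpy(dtype=float),
                grp["dbp90"].to_numpy(dtype=float),
            )

    def thresholds(self, sex: str, age_years: int, height_cm: float) -> tuple[float, float]:
        """(sbp90, dbp90) for one child; clamps out-of-band heights with a warning."""
        key = (sex, int(age_years))
        if int(age_years) >= 18:
            raise ReferenceCoverageError(
                "BP reference covers ages 6-17; use the static 130/85 mmHg rule at age 18"
            )
        if key not in self._cells:
            raise ReferenceCoverageError(f"no BP reference cell for (sex={sex}, age={age_years})")
        lows, highs, sbp, dbp = self._cells[key]
        idx = int(np.searchsorted(lows, height_cm, side="right")) - 1
        if idx < 0 or (idx == len(lows) - 1 and height_cm >= highs[-1]):
            clamped = int(np.clip(idx, 0, len(lows) - 1))
            logger.warning(
                "height %.1f cm outside BP-reference bands for (%s, %d); clamped to band %d",
                height_cm, sex, age_years, clamped,
            )
            idx = clamped
        return float(sbp[idx]), float(dbp[idx])

    def lookup_frame(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised (sbp90, dbp90) arrays for a cohort frame; ages must be 6-17."""
        sbp_out = np.empty(len(df), dtype=float)
        dbp_out = np.empty(len(df), dtype=float)
        ages = df["age_years"].to_numpy()
        if (ages >= 18).any():
            raise ReferenceCoverageError("BP reference lookups are defined for ages 6-17 only")
        clamped = 0
        for (sex, age), grp in df.groupby(["sex", "age_years"]):
            lows, highs, sbp, dbp = self._cells[(sex, int(age))]
            h = grp["height_cm"].to_numpy(dtype=float)
            idx = np.searchsorted(lows, h, side="right") - 1
            clamped += int(np.sum((idx < 0) | (h >= highs[-1])))
            idx = np.clip(idx, 0, len(lows) - 1)
            sbp_out[grp.index.to_numpy()] = sbp[idx]
            dbp_out[grp.index.to_numpy()] = dbp[idx]
        if clamped:
            logger.warning("%d height(s) outside BP-reference bands; clamped to nearest band", clamped)
        return sbp_out, dbp_out


def load_growth_reference(path) -> GrowthReferenceTable:
    """Load and validate a growth reference CSV (sex, age, six boundary columns)."""
    return GrowthReferenceTable(pd.read_csv(Path(path)))


def load_bp_reference(path) -> BPReferenceTable:
    """Load and validate a BP reference CSV (sex, age, height band, sbp90, dbp90)."""
    return BPReferenceTable(pd.read_csv(Path(path)))


def classify_weight_status(sex: str, age_years, bmi, ref: GrowthReferenceTable) -> WeightStatus:
    """Weight-status category whose half-open BMI interval contains ``bmi``.

    A BMI exactly equal to a boundary belongs to the heavier category.
    """
    return ref.classify(sex, age_years, bmi)


def bp_thresholds(sex: str, age_years: int, height_cm: float, ref: BPReferenceTable):
    """SBP/DBP 90th-percentile pair for the height band containing ``height_cm``."""
    return ref.thresholds(sex, age_years, height_cm)
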