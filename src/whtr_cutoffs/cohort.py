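"""Participant records, the cohort container, CSV I/O and unit conversion.

A cohort is a validated, ordered table of children/adolescents (6-18 completed
years) with anthropometry (height, weight, waist circumference), blood
pressure, and fasting biomarkers (triglycerides, HDL-C, glucose).  Derived
indices are computed on ingest:

* BMI  = weight_kg / (height_cm / 100)**2            [kg/m^2]
* WHtR = waist_cm / height_cm                        [dimensionless]

Canonical internal units are mg/dL for analytes, cm, kg and mmHg; any unit
conversion happens only at the I/O boundary (see :func:`read_cohort` and
:func:`convert_units`).  Rejected rows are reported with row-indexed
diagnostics, never silently imputed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import CohortValidationError, SchemaError

logger = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"

#: Accepted spellings at the I/O boundary; "1" codes male, "2" codes female.
SEX_ALIASES = {
    "m": MALE,
    "male": MALE,
    "1": MALE,
    "f": FEMALE,
    "female": FEMALE,
    "2": FEMALE,
}

REQUIRED_COLUMNS = (
    "id",
    "age_years",
    "sex",
    "height_cm",
    "weight_kg",
    "waist_cm",
    "sbp_mmHg",
    "dbp_mmHg",
    "tg_mgdl",
    "hdl_mgdl",
    "fbg_mgdl",
)
OPTIONAL_COLUMNS = ("country", "survey_year")
NUMERIC_COLUMNS = (
    "height_cm",
    "weight_kg",
    "waist_cm",
    "sbp_mmHg",
    "dbp_mmHg",
    "tg_mgdl",
    "hdl_mgdl",
    "fbg_mgdl",
)

AGE_MIN = 6
AGE_MAX = 18

# mg/dL per mmol/L
_CONVERSION_FACTORS = {"tg": 88.57, "hdl": 38.67, "fbg": 18.016}
_UNITS = ("mg/dL", "mmol/L")


@dataclasses.dataclass(frozen=True)
class DerivedIndices:
    """BMI (kg/m^2) and WHtR (waist/height, dimensionless) for one record."""

    bmi: float
    whtr: float


@dataclasses.dataclass(frozen=True)
class ParticipantRecord:
    """One child's anthropometry and fasting biomarkers, in canonical units."""

    id: str
    age_years: int
    sex: str
    height_cm: float
    weight_kg: float
    waist_cm: float
    sbp_mmHg: float
    dbp_mmHg: float
    tg_mgdl: float
    hdl_mgdl: float
    fbg_mgdl: float
    country: str | None = None
    survey_year: int | None = None

    @property
    def derived(self) -> DerivedIndices:
        return DerivedIndices(
            bmi=self.weight_kg / (self.height_cm / 100.0) ** 2,
            whtr=self.waist_cm / self.height_cm,
        )


def compute_derived(df: pd.DataFrame) -> pd.DataFrame:
    """Return ``df`` with ``bmi`` and ``whtr`` columns (re)computed from raw fields."""
    out = df.copy()
    out["bmi"] = out["weight_kg"] / (out["height_cm"] / 100.0) ** 2
    out["whtr"] = out["waist_cm"] / out["height_cm"]
    return out


def validate_rows(df: pd.DataFrame) -> list[tuple[int, str]]:
    """Vectorised invariant checks; returns ``(positional row index, message)`` pairs."""
    diagnostics: list[tuple[int, str]] = []

    def flag(mask: np.ndarray, message: str) -> None:
        for i in np.nonzero(np.asarray(mask))[0]:
            diagnostics.append((int(i), message))

    sex = df["sex"].to_numpy()
    flag(~np.isin(sex, [MALE, FEMALE]), "sex must be 'male' or 'female'")

    age = pd.to_numeric(df["age_years"], errors="coerce").to_numpy(dtype=float)
    flag(np.isnan(age) | (age != np.floor(age)), "age_years must be an integer")
    with np.errstate(invalid="ignore"):
        flag(
            ~np.isnan(age) & ((age < AGE_MIN) | (age > AGE_MAX)),
            f"age_years outside [{AGE_MIN}, {AGE_MAX}]",
        )

    for col in NUMERIC_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        flag(np.isnan(vals), f"{col} is missing or non-numeric")
        with np.errstate(invalid="ignore"):
            flag(~np.isnan(vals) & (vals <= 0), f"{col} must be strictly positive")

    height = pd.to_numeric(df["height_cm"], errors="coerce").to_numpy(dtype=float)
    waist = pd.to_numeric(df["waist_cm"], errors="coerce").to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (~np.isnan(height)) & (~np.isnan(waist)) & (waist >= 2.0 * height)
    flag(bad, "waist_cm must be < 2 * height_cm")

    diagnostics.sort(key=lambda t: t[0])
    return diagnostics


class Cohort:
    """An ordered collection of validated participant records.

    Wraps a :class:`pandas.DataFrame` with the canonical columns plus derived
    ``bmi`` and ``whtr``.  IDs are unique within a cohort.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        label: str = "",
        metadata: Mapping | None = None,
        validate: bool = True,
    ):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        df = data.reset_index(drop=True).copy()
        df["id"] = df["id"].astype(str)
        if validate:
            diagnostics = validate_rows(df)
            if diagnostics:
                raise CohortValidationError(diagnostics)
            if df["id"].duplicated().any():
                dupes = df.loc[df["id"].duplicated(), "id"].unique()[:5].tolist()
                raise CohortValidationError(
                    [(-1, f"duplicate ids within cohort: {dupes}")]
                )
        df["age_years"] = df["age_years"].astype(int)
        for col in NUMERIC_COLUMNS:
            df[col] = df[col].astype(float)
        self.df = compute_derived(df)
        self.label = label
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask, label: str | None = None) -> "Cohort":
        """Row subset sharing this cohort's provenance; skips re-validation."""
        sub = Cohort.__new__(Cohort)
        sub.df = self.df.loc[np.asarray(mask)].reset_index(drop=True)
        sub.label = label if label is not None else self.label
        sub.metadata = dict(self.metadata)
        return sub

    def records(self) -> Iterator[ParticipantRecord]:
        for row in self.df.itertuples(index=False):
            yield ParticipantRecord(
                id=row.id,
                age_years=int(row.age_years),
                sex=row.sex,
                height_cm=row.height_cm,
                weight_kg=row.weight_kg,
                waist_cm=row.waist_cm,
                sbp_mmHg=row.sbp_mmHg,
                dbp_mmHg=row.dbp_mmHg,
                tg_mgdl=row.tg_mgdl,
                hdl_mgdl=row.hdl_mgdl,
                fbg_mgdl=row.fbg_mgdl,
                country=getattr(row, "country", None),
                survey_year=getattr(row, "survey_year", None),
            )


def convert_units(value, analyte: str, from_unit: str, to_unit: str):
    """Convert an analyte concentration between mg/dL and mmol/L.

    Fixed molar factors (mg/dL per mmol/L): TG 88.57, cholesterol (HDL) 38.67,
    glucose 18.016.  Round trips return the input to ~1e-9 relative.
    """
    if analyte not in _CONVERSION_FACTORS:
        raise SchemaError(f"unknown analyte {analyte!r}; expected one of {sorted(_CONVERSION_FACTORS)}")
    if from_unit not in _UNITS or to_unit not in _UNITS:
        raise SchemaError(f"unsupported unit pair ({from_unit!r}, {to_unit!r}); supported: {_UNITS}")
    if from_unit == to_unit:
        return value
    factor = _CONVERSION_FACTORS[analyte]
    if from_unit == "mmol/L":
        return np.multiply(value, factor)
    return np.divide(value, factor)


def _load_schema(schema) -> dict:
    if schema is None:
        return {}
    if isinstance(schema, (str, Path)):
        path = Path(schema)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return json.loads(text)
        return yaml.safe_load(text)
    return dict(schema)


def read_cohort(
    path,
    schema=None,
    label: str | None = None,
    on_invalid: str = "raise",
) -> Cohort:
    """Read a cohort from a headered CSV file.

    Parameters
    ----------
    path
        CSV file with one row per participant, UTF-8, "." decimal point.
    schema
        Optional column-mapping config (mapping, YAML or JSON path) with keys:
        ``columns``: canonical name -> source column name; ``units``: analyte
        (tg/hdl/fbg) -> source unit ("mmol/L" triggers conversion to mg/dL).
    label
        Cohort label; defaults to the file stem.
    on_invalid
        ``"raise"`` (default) aborts with row-indexed diagnostics;
        ``"drop"`` removes offending rows and logs each diagnostic.

    Age is truncated to completed integer years on ingest.
    """
    path = Path(path)
    cfg = _load_schema(schema)
    mapping = dict(cfg.get("columns", {}))
    units = dict(cfg.get("units", {}))

    raw = pd.read_csv(path, dtype=str)
    rename = {}
    for canonical in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
        source = mapping.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
        elif canonical in REQUIRED_COLUMNS:
            raise SchemaError(
                f"column {source!r} (for {canonical!r}) not found in {path.name}; "
                f"available: {list(raw.columns)}"
            )
    df = raw.rename(columns=rename)
    keep = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep]

    # Normalise sex spellings; unknown codes surface as validation errors.
    df["sex"] = (
        df["sex"].astype(str).str.strip().str.lower().map(SEX_ALIASES).fillna(df["sex"])
    )
    # Completed years: truncate fractional ages.
    age_raw = pd.to_numeric(df["age_years"], errors="coerce")
    df["age_years"] = np.floor(age_raw).where(age_raw.notna())
    for col in NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "survey_year" in df.columns:
        df["survey_year"] = pd.to_numeric(df["survey_year"], errors="coerce")

    for analyte, unit in units.items():
        col = f"{analyte}_mgdl"
        if col not in df.columns:
            raise SchemaError(f"units given for unknown analyte {analyte!r}")
        if unit != "mg/dL":
            df[col] = convert_units(df[col], analyte, unit, "mg/dL")

    diagnostics = validate_rows(df)
    if diagnostics and on_invalid == "raise":
        raise CohortValidationError(diagnostics)
    if diagnostics:
        bad = sorted({i for i, _ in diagnostics})
        for i, msg in diagnostics:
            logger.warning("%s: rejected row %d: %s", path.name, i, msg)
        df = df.drop(index=df.index[bad]).reset_index(drop=True)
    accepted, rejected = len(df), len({i for i, _ in diagnostics})
    logger.info("%s: accepted %d row(s), rejected %d", path.name, accepted, rejected)

    cohort = Cohort(df, label=label if label is not None else path.stem)
    cohort.metadata.update({"source": str(path), "accepted": accepted, "rejected": rejected})
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort (raw fields plus derived BMI/WHtR) to CSV."""
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in cohort.df.columns]
    cohort.df[cols + ["bmi", "whtr"]].to_csv(path, index=False)
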