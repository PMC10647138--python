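"""Synthetic multi-region pediatric cohorts with a planted WHtR-risk threshold.

The generator emulates the structure of a pooled multi-country school
survey: ages 6-18 (uniform completed years), both sexes, a linear
sex/age height curve with Gaussian noise, and a WHtR distribution whose
location differs between two region archetypes:

* region ``A`` (Europe/USA-like): WHtR ~ N(0.47, 0.05), planted cut-off 0.50
* region ``B`` (Asia/Africa/South-America-like): WHtR ~ N(0.44, 0.05),
  planted cut-off 0.46

Each of the four cardiometabolic components (high BP, high TG, low HDL,
high FBG) is Bernoulli with probability

    p_k(w) = expit( logit(p0_k) + jump * 1[w >= c*] + slope * max(0, w - c*) )

so risk steps up at the planted cut-off c* and keeps rising above it.
Component flags are drawn first and the continuous biomarkers are then
back-filled from truncated normals on the correct side of the generating
criteria's thresholds, which guarantees that re-flagging the generated
records reproduces the drawn flags exactly -- a purely continuous
generative model would only achieve that approximately.

Baseline probabilities default to 0.07 per component in the IDF-like
setting and 0.11 in the NCEP-like setting, calibrated (by integrating
p_k(w) over the WHtR distribution) so pooled >= 2-component clustering
prevalence sits near 7.8% and 14.8% respectively.  All randomness flows
from one seeded generator; identical config => identical cohort.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtr, ndtri

from .cohort import Cohort, FEMALE, MALE
from .criteria import Criteria, FLAG_COLUMNS
from .cutoffs import CutoffEvaluation, evaluate_static_grid, outcome_mask, select_optimal
from .errors import CalibrationError, WhtrError
from .references import (
    BOUNDARY_COLUMNS,
    BPReferenceTable,
    GrowthReferenceTable,
)

COMPONENTS = ("bp", "tg", "hdl", "fbg")

# Region archetypes: planted static cut-off and WHtR location.
_REGION_DEFAULTS = {
    "A": {"planted_cutoff": 0.50, "whtr_mean": 0.47},
    "B": {"planted_cutoff": 0.46, "whtr_mean": 0.44},
}
# Baseline per-component probabilities and pooled k=2 prevalence targets.
_CRITERIA_DEFAULTS = {
    Criteria.IDF: {"p0": 0.07, "target": 0.078},
    Criteria.NCEP: {"p0": 0.11, "target": 0.148},
}

# Height growth curve: cm at age 6 and cm/year, by sex; common SD.
_HEIGHT_CURVE = {MALE: (116.5, 4.9), FEMALE: (115.5, 4.4)}
_HEIGHT_SD = 6.0

# log-BMI model shared with the synthetic growth reference: mean rises with
# age, a positive WHtR link, and residual lognormal noise.
_LOG_BMI_SD_RESID = 0.08
_BMI_WHTR_SLOPE = 4.0
_BMI_WHTR_CENTER = 0.455
_LOG_BMI_SD_TOTAL = 0.215  # approx sqrt(resid^2 + (slope * whtr_sd)^2)


def _log_bmi_mean(age):
    return np.log(16.2 + 0.38 * (np.asarray(age, dtype=float) - 6.0))


# Null (flag-free) biomarker location/scale and plausibility bounds.
_BIOMARKER_PARAMS = {
    "tg": (85.0, 30.0, 20.0, 600.0),
    "hdl": (52.0, 10.0, 15.0, 120.0),
    "fbg": (88.0, 7.0, 50.0, 300.0),
}
_SBP_BOUNDS = (60.0, 200.0)
_DBP_BOUNDS = (30.0, 130.0)


def _sbp_mean(age):
    return 100.0 + 1.1 * (np.asarray(age, dtype=float) - 6.0)


def _dbp_mean(age):
    return 60.0 + 0.5 * (np.asarray(age, dtype=float) - 6.0)


_SBP_SD, _DBP_SD = 9.0, 7.0
# Margin keeping strict-inequality back-fills clear of their threshold.
_EPS = 1e-6


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    ``None`` fields resolve to the region/criteria archetype defaults
    described in the module docstring.
    """

    n: int = 20_000
    seed: int = 0
    region: str = "A"
    criteria: Criteria = Criteria.IDF
    planted_cutoff: float | None = None
    p0: Mapping[str, float] | None = None
    jump: float = 1.0
    slope: float = 8.0
    whtr_mean: float | None = None
    whtr_age_slope: float = 0.0
    whtr_sd: float = 0.05
    prevalence_target: float | None = None
    prevalence_tol: float = 0.05
    label: str | None = None
    survey_year: int | None = None

    def resolved(self) -> "SyntheticConfig":
        region = str(self.region).upper()
        if region not in _REGION_DEFAULTS:
            raise WhtrError(f"region must be 'A' or 'B'; got {self.region!r}")
        criteria = Criteria(self.criteria)
        cdef = _CRITERIA_DEFAULTS[criteria]
        rdef = _REGION_DEFAULTS[region]
        cutoff = self.planted_cutoff if self.planted_cutoff is not None else rdef["planted_cutoff"]
        p0 = dict(self.p0) if self.p0 is not None else {c: cdef["p0"] for c in COMPONENTS}
        target = self.prevalence_target if self.prevalence_target is not None else cdef["target"]
        cfg = dataclasses.replace(
            self,
            region=region,
            criteria=criteria,
            planted_cutoff=float(cutoff),
            p0=p0,
            whtr_mean=float(self.whtr_mean if self.whtr_mean is not None else rdef["whtr_mean"]),
            prevalence_target=float(target),
            label=self.label if self.label is not None else f"region{region}",
        )
        if not (0.40 <= cfg.planted_cutoff <= 0.56):
            raise WhtrError(f"planted cutoff must lie in [0.40, 0.56]; got {cfg.planted_cutoff}")
        if cfg.n < 0:
            raise WhtrError("n must be non-negative")
        if set(cfg.p0) != set(COMPONENTS) or not all(0.0 < v < 1.0 for v in cfg.p0.values()):
            raise WhtrError(f"p0 must give a probability in (0,1) for each of {COMPONENTS}")
        return cfg


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Planted parameters, sufficient to recompute every record's component
    probabilities, serialized alongside the cohort.

    ``drawn_flags`` holds the realized component flags (not serialized);
    re-flagging the cohort under the generating criteria must reproduce them
    exactly.
    """

    planted_cutoff: float
    jump: float
    slope: float
    p0: dict[str, float]
    criteria: str
    region: str
    whtr_mean: float
    whtr_age_slope: float
    whtr_sd: float
    seed: int
    n: int
    drawn_flags: pd.DataFrame | None = dataclasses.field(default=None, repr=False, compare=False)

    def component_probability(self, whtr, component: str) -> np.ndarray:
        w = np.asarray(whtr, dtype=float)
        eta = (
            logit(self.p0[component])
            + self.jump * (w >= self.planted_cutoff)
            + self.slope * np.maximum(0.0, w - self.planted_cutoff)
        )
        return expit(eta)

    def to_json(self, path) -> None:
        payload = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "drawn_flags"
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    """Inverse-CDF sampling of N(mean, sd) truncated to (lo, hi); vectorised."""
    mean = np.asarray(mean, dtype=float)
    a = ndtr((np.asarray(lo, dtype=float) - mean) / sd)
    b = ndtr((np.asarray(hi, dtype=float) - mean) / sd)
    u = rng.uniform(a, b) if size is None else rng.uniform(a, b, size=size)
    u = np.clip(u, 1e-15, np.nextafter(1.0, 0.0))
    return mean + sd * ndtri(u)


def generate_reference_tables(seed: int = 0) -> tuple[GrowthReferenceTable, BPReferenceTable]:
    """Synthetic growth and BP reference tables of the published tables' shape.

    BMI boundaries follow the generator's own log-BMI model at fixed z-scores
    (so weight-status mix lands near the thin 13% / overweight 17% / obese 7%
    regime of pooled school surveys); BP 90th percentiles follow the SBP/DBP
    age curves with a mild height-band gradient.  These are synthetic
    stand-ins with the correct structure, not published reference values.
    """
    rng = np.random.default_rng(seed)
    z_scores = dict(
        zip(BOUNDARY_COLUMNS, (-2.17, -1.75, -1.11, 0.70, 1.47, 2.40))
    )
    rows = []
    for sex, sex_factor in ((MALE, 1.0), (FEMALE, 0.995)):
        for age in range(6, 19):
            mean = _log_bmi_mean(age) + np.log(sex_factor)
            jitter = rng.normal(0.0, 0.002, size=len(BOUNDARY_COLUMNS))
            row = {"sex": sex, "age": age}
            for (col, z), j in zip(z_scores.items(), jitter):
                row[col] = float(np.exp(mean + z * _LOG_BMI_SD_TOTAL + j))
            rows.append(row)
    growth = GrowthReferenceTable(pd.DataFrame(rows))

    bp_rows = []
    band_offsets = (-30.0, -9.0, -3.0, 3.0, 9.0, 30.0)
    for sex in (MALE, FEMALE):
        base, rate = _HEIGHT_CURVE[sex]
        for age in range(6, 18):
            mu_h = base + rate * (age - 6)
            sbp_base = float(_sbp_mean(age) + 1.2816 * _SBP_SD)
            dbp_base = float(_dbp_mean(age) + 1.2816 * _DBP_SD)
            for b in range(5):
                bp_rows.append(
                    {
                        "sex": sex,
                        "age": age,
                        "height_low": mu_h + band_offsets[b],
                        "height_high": mu_h + band_offsets[b + 1],
                        "sbp90": sbp_base + 0.8 * (b - 2) + float(rng.normal(0, 0.1)),
                        "dbp90": dbp_base + 0.5 * (b - 2) + float(rng.normal(0, 0.1)),
                    }
                )
    bp = BPReferenceTable(pd.DataFrame(bp_rows))
    return growth, bp


def expected_clustering_prevalence(config: SyntheticConfig, k: int = 2) -> float:
    """Pooled P(count >= k) implied by a config, by numerical integration
    of the component model over the truncated WHtR distribution."""
    cfg = config.resolved()
    ages = np.arange(6, 19, dtype=float)
    grid = np.linspace(0.30, 0.80, 501)
    total = 0.0
    for age in ages:
        mean = cfg.whtr_mean + cfg.whtr_age_slope * (age - 12.0)
        z = (grid - mean) / cfg.whtr_sd
        dens = np.exp(-0.5 * z**2)
        dens /= dens.sum()
        probs = np.stack(
            [
                expit(
                    logit(cfg.p0[c])
                    + cfg.jump * (grid >= cfg.planted_cutoff)
                    + cfg.slope * np.maximum(0.0, grid - cfg.planted_cutoff)
                )
                for c in COMPONENTS
            ]
        )
        # P(count >= k | w) over the four independent components.
        p_ge = np.zeros_like(grid)
        for pattern in range(16):
            bits = [(pattern >> i) & 1 for i in range(4)]
            if sum(bits) < k:
                continue
            term = np.ones_like(grid)
            for bit, p in zip(bits, probs):
                term = term * (p if bit else (1.0 - p))
            p_ge += term
        total += float(np.sum(dens * p_ge))
    return total / len(ages)


def _bp_thresholds_for(df: pd.DataFrame, criteria: Criteria, bp_ref: BPReferenceTable):
    age = df["age_years"].to_numpy()
    if criteria is Criteria.IDF:
        sbp_thr = np.where(age <= 9, 120.0, 130.0)
        dbp_thr = np.where(age <= 9, 80.0, 85.0)
        return sbp_thr, dbp_thr
    sbp_thr = np.full(len(df), 130.0)
    dbp_thr = np.full(len(df), 85.0)
    child = age < 18
    if child.any():
        sub = df.loc[child].reset_index(drop=True)
        sbp90, dbp90 = bp_ref.lookup_frame(sub)
        sbp_thr[child] = sbp90
        dbp_thr[child] = dbp90
    return sbp_thr, dbp_thr


def generate_cohort(
    config: SyntheticConfig,
    growth_ref: GrowthReferenceTable | None = None,
    bp_ref: BPReferenceTable | None = None,
) -> tuple[Cohort, SyntheticTruth]:
    """Draw one synthetic cohort and the ground truth that generated it.

    The draw order is fixed (age, sex, height, WHtR, BMI noise, component
    flags, BP channel, biomarkers), so identical config => byte-identical
    cohort.  Raises :class:`CalibrationError` when the config's implied
    pooled clustering prevalence misses its target by more than
    ``prevalence_tol``.
    """
    cfg = config.resolved()
    implied = expected_clustering_prevalence(cfg, k=2)
    if abs(implied - cfg.prevalence_target) > cfg.prevalence_tol:
        raise CalibrationError(
            f"config implies pooled k=2 prevalence {implied:.3f}, target "
            f"{cfg.prevalence_target:.3f} (tol {cfg.prevalence_tol})"
        )
    if bp_ref is None and cfg.criteria is Criteria.NCEP:
        _, bp_ref = generate_reference_tables(cfg.seed)

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    truth_kwargs = dict(
        planted_cutoff=cfg.planted_cutoff,
        jump=cfg.jump,
        slope=cfg.slope,
        p0=dict(cfg.p0),
        criteria=cfg.criteria.value,
        region=cfg.region,
        whtr_mean=cfg.whtr_mean,
        whtr_age_slope=cfg.whtr_age_slope,
        whtr_sd=cfg.whtr_sd,
        seed=cfg.seed,
        n=n,
    )
    if n == 0:
        columns = [
            ("id", str), ("age_years", int), ("sex", str), ("height_cm", float),
            ("weight_kg", float), ("waist_cm", float), ("sbp_mmHg", float),
            ("dbp_mmHg", float), ("tg_mgdl", float), ("hdl_mgdl", float),
            ("fbg_mgdl", float), ("country", str),
        ]
        empty = pd.DataFrame({c: pd.Series(dtype=t) for c, t in columns})
        cohort = Cohort(empty, label=cfg.label, validate=False)
        return cohort, SyntheticTruth(**truth_kwargs, drawn_flags=pd.DataFrame(columns=FLAG_COLUMNS))

    age = rng.integers(6, 19, size=n)
    sex = np.where(rng.integers(0, 2, size=n) == 1, MALE, FEMALE)
    h_base = np.where(sex == MALE, _HEIGHT_CURVE[MALE][0], _HEIGHT_CURVE[FEMALE][0])
    h_rate = np.where(sex == MALE, _HEIGHT_CURVE[MALE][1], _HEIGHT_CURVE[FEMALE][1])
    height = h_base + h_rate * (age - 6) + rng.normal(0.0, _HEIGHT_SD, size=n)

    whtr_mu = cfg.whtr_mean + cfg.whtr_age_slope * (age - 12.0)
    whtr = _truncated_normal(rng, whtr_mu, cfg.whtr_sd, 0.30, 0.80)
    waist = whtr * height

    log_bmi = (
        _log_bmi_mean(age)
        + _BMI_WHTR_SLOPE * (whtr - _BMI_WHTR_CENTER)
        + rng.normal(0.0, _LOG_BMI_SD_RESID, size=n)
    )
    bmi = np.exp(log_bmi)
    weight = bmi * (height / 100.0) ** 2

    truth = SyntheticTruth(**truth_kwargs)
    p = np.stack([truth.component_probability(whtr, c) for c in COMPONENTS], axis=1)
    flags = rng.random((n, 4)) < p  # columns follow COMPONENTS order
    flag_bp, flag_tg, flag_hdl, flag_fbg = flags.T

    df = pd.DataFrame({"sex": sex, "age_years": age, "height_cm": height})
    sbp_thr, dbp_thr = _bp_thresholds_for(df, cfg.criteria, bp_ref)
    sbp_channel = rng.random(n) < 0.75  # which BP component carries the exceedance

    sbp = np.empty(n)
    dbp = np.empty(n)
    sbp_mu, dbp_mu = _sbp_mean(age), _dbp_mean(age)
    hi_s = flag_bp & sbp_channel
    hi_d = flag_bp & ~sbp_channel
    lo = ~flag_bp
    sbp[hi_s] = _truncated_normal(rng, sbp_mu[hi_s], _SBP_SD, sbp_thr[hi_s], _SBP_BOUNDS[1])
    dbp[hi_s] = _truncated_normal(rng, dbp_mu[hi_s], _DBP_SD, _DBP_BOUNDS[0], dbp_thr[hi_s] - _EPS)
    sbp[hi_d] = _truncated_normal(rng, sbp_mu[hi_d], _SBP_SD, _SBP_BOUNDS[0], sbp_thr[hi_d] - _EPS)
    dbp[hi_d] = _truncated_normal(rng, dbp_mu[hi_d], _DBP_SD, dbp_thr[hi_d], _DBP_BOUNDS[1])
    sbp[lo] = _truncated_normal(rng, sbp_mu[lo], _SBP_SD, _SBP_BOUNDS[0], sbp_thr[lo] - _EPS)
    dbp[lo] = _truncated_normal(rng, dbp_mu[lo], _DBP_SD, _DBP_BOUNDS[0], dbp_thr[lo] - _EPS)

    # TG / FBG: flag means value >= threshold under both criteria sets.
    tg_thr = 150.0 if cfg.criteria is Criteria.IDF else 110.0
    fbg_thr = 100.0 if cfg.criteria is Criteria.IDF else 110.0
    tg = np.empty(n)
    fbg = np.empty(n)
    for arr, flag, thr, key in ((tg, flag_tg, tg_thr, "tg"), (fbg, flag_fbg, fbg_thr, "fbg")):
        mean, sd, lo_b, hi_b = _BIOMARKER_PARAMS[key]
        arr[flag] = _truncated_normal(rng, mean, sd, thr, hi_b, size=int(flag.sum()))
        arr[~flag] = _truncated_normal(rng, mean, sd, lo_b, thr - _EPS, size=int((~flag).sum()))

    # HDL: IDF flags strictly below an age/sex threshold; NCEP flags <= 40.
    if cfg.criteria is Criteria.IDF:
        hdl_thr = np.where(age <= 15, 40.0, np.where(sex == MALE, 40.0, 50.0))
        low_hi = hdl_thr - _EPS  # flag true: hdl < thr
        ok_lo = hdl_thr          # flag false: hdl >= thr
    else:
        hdl_thr = np.full(n, 40.0)
        low_hi = hdl_thr         # flag true: hdl <= thr
        ok_lo = hdl_thr + _EPS   # flag false: hdl > thr
    mean, sd, lo_b, hi_b = _BIOMARKER_PARAMS["hdl"]
    hdl = np.empty(n)
    hdl[flag_hdl] = _truncated_normal(rng, mean, sd, lo_b, low_hi[flag_hdl])
    hdl[~flag_hdl] = _truncated_normal(rng, mean, sd, ok_lo[~flag_hdl], hi_b)

    data = pd.DataFrame(
        {
            "id": [f"{cfg.label}-{i:06d}" for i in range(n)],
            "age_years": age.astype(int),
            "sex": sex,
            "height_cm": height,
            "weight_kg": weight,
            "waist_cm": waist,
            "sbp_mmHg": sbp,
            "dbp_mmHg": dbp,
            "tg_mgdl": tg,
            "hdl_mgdl": hdl,
            "fbg_mgdl": fbg,
            "country": cfg.label,
        }
    )
    if cfg.survey_year is not None:
        data["survey_year"] = cfg.survey_year
    cohort = Cohort(data, label=cfg.label, metadata={"synthetic": True, "seed": cfg.seed})
    drawn = pd.DataFrame(
        {"high_bp": flag_bp, "high_tg": flag_tg, "low_hdl": flag_hdl, "high_fbg": flag_fbg}
    )
    return cohort, dataclasses.replace(truth, drawn_flags=drawn)


@dataclasses.dataclass(frozen=True)
class RecoveryResult:
    recovered_cutoff: float
    evaluation: CutoffEvaluation
    truth: SyntheticTruth


def recover_cutoff(
    config: SyntheticConfig,
    k: int = 2,
    lo: float = 0.42,
    hi: float = 0.56,
    step: float = 0.01,
    bp_ref: BPReferenceTable | None = None,
) -> RecoveryResult:
    """Generate a cohort, grid-search static cut-offs, return the optimum.

    The recovered value is compared against the planted cut-off by the
    parameter-recovery test-suite; the outcome is clustering >= k under the
    generating criteria.
    """
    cfg = config.resolved()
    if bp_ref is None and cfg.criteria is Criteria.NCEP:
        _, bp_ref = generate_reference_tables(cfg.seed)
    cohort, truth = generate_cohort(cfg, bp_ref=bp_ref)
    y = outcome_mask(cohort, cfg.criteria, k, bp_ref)
    evals = evaluate_static_grid(cohort, cfg.criteria, k, bp_ref, lo=lo, hi=hi, step=step, outcome=y)
    best = select_optimal(evals)
    return RecoveryResult(recovered_cutoff=float(best.cutoff), evaluation=best, truth=truth)
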