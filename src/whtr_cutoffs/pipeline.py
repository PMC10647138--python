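"""End-to-end orchestration: derive cut-offs on one set of cohorts,
consolidate per region group, validate on held-out cohorts.

``run_derivation`` executes, per stratum (country cohort, optionally split
by sex): weight-status subsampling -> reference-subsample selection ->
WHtR percentile table -> percentile-candidate and/or static-grid ROC
search -> per-stratum optimum; then consolidates the static optima to one
proposed cut-off per region group.  ``run_validation`` evaluates proposed
cut-offs on independent test cohorts under both criteria and k in {2, 3}:
classifier metrics plus sex/age-adjusted odds ratios, with a pooled model
additionally adjusted for survey year.

Every decision (reference subsample chosen, tie-breaks, skipped strata)
lands in the run log; failures of individual strata are logged and
skipped, and a run fails only if every stratum fails.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, MALE, FEMALE
from .criteria import Criteria
from .cutoffs import (
    CutoffEvaluation,
    GRID_HI,
    GRID_LO,
    GRID_STEP,
    ProposedCutoffs,
    consolidate,
    evaluate_percentile_candidates,
    evaluate_static_grid,
    evaluations_to_frame,
    outcome_mask,
    select_optimal,
)
from .errors import WhtrError
from .references import BPReferenceTable, GrowthReferenceTable
from .subsamples import (
    DEFAULT_CANDIDATES,
    DEFAULT_MIN_CELL_N,
    build_subsample,
    select_reference_subsample,
    whtr_percentile_table,
)
from .validation import ORResult, fit_logistic, validate_proposed, dichotomize

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Settings for a derivation/validation run; validated up front."""

    criteria: Criteria = Criteria.IDF
    k: int = 2
    strategy: str = "both"  # percentile | grid | both
    percentile_candidates: Sequence[int] = DEFAULT_CANDIDATES
    grid_lo: float = GRID_LO
    grid_hi: float = GRID_HI
    grid_step: float = GRID_STEP
    grouping: Mapping[str, str] = dataclasses.field(default_factory=dict)
    sex_mode: str = "pooled"  # pooled | by_sex
    min_cell_n: int = DEFAULT_MIN_CELL_N
    outdir: str | Path | None = None

    def __post_init__(self):
        self.criteria = Criteria(self.criteria)
        if self.k not in (2, 3):
            raise WhtrError(f"k must be 2 or 3; got {self.k}")
        if self.strategy not in ("percentile", "grid", "both"):
            raise WhtrError(f"unknown strategy {self.strategy!r}")
        if self.sex_mode not in ("pooled", "by_sex"):
            raise WhtrError(f"unknown sex_mode {self.sex_mode!r}")


@dataclasses.dataclass
class DerivationResult:
    optima: dict[str, CutoffEvaluation]             # stratum -> static optimum
    percentile_optima: dict[str, CutoffEvaluation]  # stratum -> percentile optimum
    proposed: ProposedCutoffs | None
    subsample_tables: dict[str, pd.DataFrame]
    results: pd.DataFrame
    log: list[str]


def _strata(cohorts: Mapping[str, Cohort], sex_mode: str):
    for label, cohort in cohorts.items():
        if sex_mode == "pooled":
            yield label, label, cohort
        else:
            for sex in (MALE, FEMALE):
                yield f"{label}:{sex}", label, cohort.subset(
                    (cohort.df["sex"] == sex).to_numpy(), label=f"{label}:{sex}"
                )


def run_derivation(
    cohorts: Mapping[str, Cohort],
    config: RunConfig,
    growth_ref: GrowthReferenceTable,
    bp_ref: BPReferenceTable | None = None,
) -> DerivationResult:
    """Derive per-stratum optimal cut-offs and consolidate to proposals."""
    if not cohorts:
        raise WhtrError("at least one derivation cohort is required")
    log: list[str] = []
    optima: dict[str, CutoffEvaluation] = {}
    percentile_optima: dict[str, CutoffEvaluation] = {}
    subsample_tables: dict[str, pd.DataFrame] = {}
    frames: list[pd.DataFrame] = []

    for stratum, country, cohort in _strata(cohorts, config.sex_mode):
        try:
            ref_id, table = select_reference_subsample(
                cohort, config.criteria, config.k, bp_ref, growth_ref
            )
            subsample_tables[stratum] = table
            log.append(f"{stratum}: reference subsample {ref_id.value} "
                       f"(min clustering prevalence)")
            reference = build_subsample(cohort, ref_id, growth_ref)
            y = outcome_mask(cohort, config.criteria, config.k, bp_ref)

            if config.strategy in ("percentile", "both"):
                ptable = whtr_percentile_table(
                    reference, config.percentile_candidates, config.min_cell_n
                )
                pevals = evaluate_percentile_candidates(
                    cohort, ptable, config.percentile_candidates,
                    config.criteria, config.k, bp_ref, outcome=y,
                )
                pbest = select_optimal(pevals, log)
                percentile_optima[stratum] = pbest
                log.append(f"{stratum}: optimal percentile candidate P{pbest.cutoff} "
                           f"(Youden {pbest.youden:.3f})")
                frames.append(evaluations_to_frame(pevals, stratum))

            if config.strategy in ("grid", "both"):
                gevals = evaluate_static_grid(
                    cohort, config.criteria, config.k, bp_ref,
                    lo=config.grid_lo, hi=config.grid_hi, step=config.grid_step,
                    outcome=y,
                )
                gbest = select_optimal(gevals, log)
                optima[stratum] = gbest
                log.append(f"{stratum}: optimal static cutoff {gbest.cutoff:.2f} "
                           f"(Youden {gbest.youden:.3f})")
                frames.append(evaluations_to_frame(gevals, stratum))
        except WhtrError as exc:
            msg = f"{stratum}: skipped ({exc})"
            logger.warning(msg)
            log.append(msg)

    if not optima and not percentile_optima:
        raise WhtrError("all strata failed; see run log")

    proposed = None
    if optima and config.grouping:
        stratum_groups = {}
        for stratum in optima:
            country = stratum.split(":")[0]
            if country in config.grouping:
                stratum_groups[stratum] = config.grouping[country]
        if stratum_groups:
            proposed = consolidate(
                {s: float(optima[s].cutoff) for s in stratum_groups}, stratum_groups
            )
            log.append(f"proposed cutoffs by group: {proposed.values}")

    results = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out = DerivationResult(optima, percentile_optima, proposed, subsample_tables, results, log)
    if config.outdir is not None:
        _write_derivation(out, config)
    return out


def _write_derivation(result: DerivationResult, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.results.to_csv(outdir / "cutoff_evaluations.csv", index=False)
    if result.proposed is not None:
        result.proposed.dispersion.to_csv(outdir / "proposed_cutoffs.csv", index=False)
    pd.concat(
        [t.assign(stratum=s) for s, t in result.subsample_tables.items()],
        ignore_index=True,
    ).to_csv(outdir / "subsample_proportions.csv", index=False)
    (outdir / "run.log").write_text("\n".join(result.log) + "\n")


@dataclasses.dataclass
class ValidationResult:
    table: pd.DataFrame
    or_results: dict[tuple, ORResult]
    log: list[str]


def run_validation(
    test_cohorts: Mapping[str, Cohort],
    proposed: ProposedCutoffs,
    grouping: Mapping[str, str],
    bp_ref: BPReferenceTable | None = None,
    criteria_list: Sequence[Criteria] = (Criteria.IDF, Criteria.NCEP),
    k_values: Sequence[int] = (2, 3),
    outdir: str | Path | None = None,
) -> ValidationResult:
    """Test proposed cut-offs on held-out cohorts (classifier + adjusted OR).

    One row per cohort x criteria x k, plus pooled rows where the pooled
    logistic model is additionally adjusted for survey year when it varies.
    """
    if not proposed.values:
        raise WhtrError("no proposed cutoffs to validate")
    log: list[str] = []
    rows = []
    or_results: dict[tuple, ORResult] = {}

    for label, cohort in test_cohorts.items():
        if label not in grouping or grouping[label] not in proposed.values:
            log.append(f"{label}: skipped (no group/proposed cutoff)")
            continue
        cutoff = proposed.values[grouping[label]]
        for criteria in criteria_list:
            for k in k_values:
                try:
                    ev, orres = validate_proposed(cohort, cutoff, criteria, k, bp_ref)
                except WhtrError as exc:
                    msg = f"{label}/{Criteria(criteria).value}/k={k}: skipped ({exc})"
                    logger.warning(msg)
                    log.append(msg)
                    continue
                or_results[(label, Criteria(criteria).value, k)] = orres
                rows.append(
                    {
                        "cohort": label, "cutoff": cutoff,
                        "criteria": Criteria(criteria).value, "k": k,
                        "auc": ev.auc, "sens": ev.sens, "spec": ev.spec,
                        "or": orres.odds_ratio,
                        "or_lo": orres.ci[0], "or_hi": orres.ci[1],
                        "n": ev.n, "converged": orres.converged,
                    }
                )

    pooled = _pooled_validation(test_cohorts, proposed, grouping, bp_ref, criteria_list, k_values, log)
    for key, (row, orres) in pooled.items():
        or_results[key] = orres
        rows.append(row)

    table = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "validation.csv", index=False)
        (outdir / "validation.log").write_text("\n".join(log) + "\n")
    return ValidationResult(table, or_results, log)


def _pooled_validation(test_cohorts, proposed, grouping, bp_ref, criteria_list, k_values, log):
    usable = {
        label: cohort
        for label, cohort in test_cohorts.items()
        if label in grouping and grouping[label] in proposed.values
    }
    if len(usable) < 2:
        return {}
    frames = []
    exposures = []
    for label, cohort in usable.items():
        cutoff = proposed.values[grouping[label]]
        frames.append(cohort.df.assign(_cohort=label))
        exposures.append(dichotomize(cohort, cutoff))
    pooled_df = pd.concat(frames, ignore_index=True)
    pooled = Cohort(pooled_df.drop(columns=["_cohort"]), label="pooled", validate=False)
    exposure = np.concatenate(exposures)
    covariates = pd.DataFrame(
        {
            "male": (pooled_df["sex"] == MALE).astype(float),
            "age_years": pooled_df["age_years"].astype(float),
        }
    )
    if "survey_year" in pooled_df.columns and pooled_df["survey_year"].nunique(dropna=True) > 1:
        covariates["survey_year"] = pooled_df["survey_year"].astype(float)

    out = {}
    for criteria in criteria_list:
        for k in k_values:
            try:
                y = outcome_mask(pooled, criteria, k, bp_ref)
                orres = fit_logistic(y, exposure, covariates)
            except WhtrError as exc:
                log.append(f"pooled/{Criteria(criteria).value}/k={k}: skipped ({exc})")
                continue
            row = {
                "cohort": "pooled", "cutoff": np.nan,
                "criteria": Criteria(criteria).value, "k": k,
                "auc": np.nan, "sens": np.nan, "spec": np.nan,
                "or": orres.odds_ratio, "or_lo": orres.ci[0], "or_hi": orres.ci[1],
                "n": orres.n, "converged": orres.converged,
            }
            out[("pooled", Criteria(criteria).value, k)] = (row, orres)
    return out
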