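"""Weight-status subsamples, reference selection, WHtR percentile tables."""

import numpy as np
import pandas as pd
import pytest

from whtr_cutoffs.cohort import Cohort
from whtr_cutoffs.criteria import Criteria
from whtr_cutoffs.errors import MissingCellError, SparseCellError
from whtr_cutoffs.references import WeightStatus
from whtr_cutoffs.subsamples import (
    MEMBERSHIP,
    SubsampleId,
    build_subsample,
    exceeds_percentile,
    select_reference_subsample,
    weight_status_series,
    whtr_percentile_table,
)
from whtr_cutoffs.synthetic import SyntheticConfig, generate_cohort

from conftest import make_cohort_frame


def cohort_with_statuses(growth_ref, statuses, sex="male", age=10):
    """Build a cohort whose BMI places each record in the given status."""
    row = growth_ref.df[(growth_ref.df["sex"] == sex) & (growth_ref.df["age"] == age)].iloc[0]
    edges = [row.thin3, row.thin2, row.thin1, row.overweight, row.obesity, row.morbid_obesity]
    mids = {
        WeightStatus.THIN3: edges[0] - 1,
        WeightStatus.THIN2: (edges[0] + edges[1]) / 2,
        WeightStatus.THIN1: (edges[1] + edges[2]) / 2,
        WeightStatus.NORMAL: (edges[2] + edges[3]) / 2,
        WeightStatus.OVERWEIGHT: (edges[3] + edges[4]) / 2,
        WeightStatus.OBESE: (edges[4] + edges[5]) / 2,
        WeightStatus.MORBID_OBESE: edges[5] + 2,
    }
    height = 140.0
    rows = [
        {"sex": sex, "age_years": age, "height_cm": height,
         "weight_kg": mids[s] * (height / 100) ** 2, "waist_cm": 63.0}
        for s in statuses
    ]
    return Cohort(make_cohort_frame(rows))


class TestBuildSubsample:
    def test_membership_sizes(self, growth_ref):
        cohort = cohort_with_statuses(
            growth_ref,
            [WeightStatus.THIN1, WeightStatus.NORMAL, WeightStatus.NORMAL,
             WeightStatus.OVERWEIGHT, WeightStatus.OBESE],
        )
        sizes = {sid: len(build_subsample(cohort, sid, growth_ref)) for sid in SubsampleId}
        assert sizes[SubsampleId.S2] == 2
        assert sizes[SubsampleId.S3] == 4
        assert sizes[SubsampleId.S5] == 3
        assert sizes[SubsampleId.S4] == 4
        assert sizes[SubsampleId.S1] == 5

    def test_s1_is_identity(self, growth_ref, small_cohort):
        assert len(build_subsample(small_cohort, SubsampleId.S1, growth_ref)) == len(small_cohort)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nesting_chain_on_fuzzed_cohorts(self, growth_ref, bp_ref, seed):
        cohort, _ = generate_cohort(
            SyntheticConfig(n=800, seed=seed, region="A", criteria="IDF"), growth_ref, bp_ref
        )
        ids = {
            sid: set(build_subsample(cohort, sid, growth_ref).df["id"]) for sid in SubsampleId
        }
        assert ids[SubsampleId.S2] <= ids[SubsampleId.S5] <= ids[SubsampleId.S4] <= ids[SubsampleId.S6] <= ids[SubsampleId.S1]
        assert ids[SubsampleId.S2] <= ids[SubsampleId.S3] <= ids[SubsampleId.S1]


class TestSelectReferenceSubsample:
    def test_risk_gradient_selects_normal_weight(self, growth_ref, bp_ref):
        cohort, _ = generate_cohort(
            SyntheticConfig(n=6000, seed=5, region="A", criteria="IDF"), growth_ref, bp_ref
        )
        sid, table = select_reference_subsample(cohort, Criteria.IDF, 2, bp_ref, growth_ref)
        assert sid is SubsampleId.S2
        assert table["proportion"].between(0, 1).all()

    def test_argmin_not_exceeded_by_any_subsample(self, growth_ref, bp_ref):
        cohort, _ = generate_cohort(
            SyntheticConfig(n=3000, seed=6, region="B", criteria="IDF"), growth_ref, bp_ref
        )
        sid, table = select_reference_subsample(cohort, Criteria.IDF, 2, bp_ref, growth_ref)
        chosen = table.loc[table["subsample"] == sid.value, "proportion"].iloc[0]
        assert (chosen <= table["proportion"]).all()

    def test_identical_flags_tie_breaks_to_s2(self, growth_ref):
        # everyone flagged identically (high TG + high FBG) -> all proportions 1.0
        cohort = cohort_with_statuses(
            growth_ref,
            [WeightStatus.THIN1, WeightStatus.NORMAL, WeightStatus.OVERWEIGHT,
             WeightStatus.OBESE, WeightStatus.MORBID_OBESE, WeightStatus.THIN2,
             WeightStatus.THIN3],
        )
        cohort.df[["tg_mgdl", "fbg_mgdl"]] = [160.0, 105.0]
        sid, table = select_reference_subsample(cohort, Criteria.IDF, 2, None, growth_ref)
        assert sid is SubsampleId.S2
        assert (table["proportion"] == 1.0).all()


def manual_linear_quantile(values, p):
    """Independent order-statistic oracle: 0-based h = (n-1) * p/100 with
    linear interpolation between the bracketing order statistics."""
    x = np.sort(np.asarray(values, dtype=float))
    h = (len(x) - 1) * (p / 100.0)
    lo = int(np.floor(h))
    hi = min(lo + 1, len(x) - 1)
    return x[lo] + (h - lo) * (x[hi] - x[lo])


def cohort_with_whtr(whtr_values, sex="male", age=10):
    height = 150.0
    rows = [
        {"sex": sex, "age_years": age, "height_cm": height, "waist_cm": w * height}
        for w in whtr_values
    ]
    return Cohort(make_cohort_frame(rows))


class TestPercentileTable:
    def test_two_point_cell_matches_convention_formula(self, growth_ref):
        cohort = cohort_with_whtr([0.40] * 50 + [0.60] * 50)
        table = whtr_percentile_table(cohort)
        expected = manual_linear_quantile([0.40] * 50 + [0.60] * 50, 75)
        assert table.lookup("male", 10, 75) == pytest.approx(expected)
        assert 0.40 <= table.lookup("male", 10, 75) <= 0.60

    def test_constant_cell_gives_constant_percentiles(self):
        table = whtr_percentile_table(cohort_with_whtr([0.45] * 30))
        for p in (75, 80, 85, 90, 95):
            assert table.lookup("male", 10, p) == pytest.approx(0.45)

    def test_uniform_sample_p90_near_090(self):
        rng = np.random.default_rng(0)
        # WHtR must stay in (0, 2); uniform(0.30, 0.70) has known quantiles
        vals = rng.uniform(0.30, 0.70, size=20_000)
        table = whtr_percentile_table(cohort_with_whtr(vals))
        assert table.lookup("male", 10, 90) == pytest.approx(0.30 + 0.9 * 0.4, abs=0.005)

    def test_sparse_cell_errors_listing_cells(self):
        cohort = cohort_with_whtr([0.45] * 5)
        with pytest.raises(SparseCellError) as err:
            whtr_percentile_table(cohort, min_cell_n=10)
        assert "(male, 10)" in str(err.value)

    def test_monotone_in_p_within_cells(self, growth_ref, bp_ref):
        cohort, _ = generate_cohort(
            SyntheticConfig(n=2000, seed=9, region="A", criteria="IDF"), growth_ref, bp_ref
        )
        table = whtr_percentile_table(cohort, min_cell_n=10)
        for (_, _), grp in table.df.groupby(["sex", "age"]):
            vals = grp.sort_values("p")["value"].to_numpy()
            assert np.all(np.diff(vals) >= 0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_sort_based_oracle_on_random_cohorts(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(40, 1000))
        vals = rng.normal(0.47, 0.05, size=n).clip(0.31, 0.79)
        table = whtr_percentile_table(cohort_with_whtr(vals))
        for p in (75, 80, 85, 90, 95):
            assert table.lookup("male", 10, p) == pytest.approx(
                manual_linear_quantile(vals, p), rel=1e-12
            )

    def test_duplication_invariance_of_inverted_cdf_convention(self):
        rng = np.random.default_rng(3)
        vals = list(rng.uniform(0.35, 0.65, size=57))
        t1 = whtr_percentile_table(cohort_with_whtr(vals), method="inverted_cdf")
        t2 = whtr_percentile_table(cohort_with_whtr(vals * 2), method="inverted_cdf")
        for p in (75, 80, 85, 90, 95):
            assert t1.lookup("male", 10, p) == t2.lookup("male", 10, p)


class TestExceedsPercentile:
    def test_boundary_is_inclusive(self):
        cohort = cohort_with_whtr([0.45] * 30)
        table = whtr_percentile_table(cohort)
        rec = next(cohort.records())
        assert exceeds_percentile(rec, table, 90) is True  # whtr == cell value

    def test_below_p75_fails_all_candidates(self):
        table = whtr_percentile_table(cohort_with_whtr(list(np.linspace(0.45, 0.55, 40))))
        low = cohort_with_whtr([0.40])
        for p in (75, 80, 85, 90, 95):
            assert not exceeds_percentile(low, table, p).any()

    def test_missing_cell_errors(self):
        table = whtr_percentile_table(cohort_with_whtr([0.45] * 30, age=10))
        other_age = cohort_with_whtr([0.45], age=11)
        with pytest.raises(MissingCellError):
            exceeds_percentile(other_age, table, 75)

    def test_vector_path_matches_direct_lookup(self, growth_ref, bp_ref):
        cohort, _ = generate_cohort(
            SyntheticConfig(n=1000, seed=12, region="B", criteria="IDF"), growth_ref, bp_ref
        )
        table = whtr_percentile_table(cohort, min_cell_n=5)
        mask = exceeds_percentile(cohort, table, 85)
        for i, rec in enumerate(cohort.records()):
            assert mask[i] == (rec.derived.whtr >= table.lookup(rec.sex, rec.age_years, 85))
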