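"""Cut-off evaluation: confusion tallies, ROC identities, grid, consolidation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from whtr_cutoffs.cohort import Cohort
from whtr_cutoffs.criteria import Criteria
from whtr_cutoffs.cutoffs import (
    ConfusionCounts,
    confusion_at,
    consolidate,
    evaluate_cutoff,
    evaluate_percentile_candidates,
    evaluate_static_grid,
    select_optimal,
    static_grid,
)
from whtr_cutoffs.errors import DegenerateOutcomeError, WhtrError
from whtr_cutoffs.subsamples import whtr_percentile_table
from whtr_cutoffs.synthetic import SyntheticConfig, generate_cohort

from conftest import make_cohort_frame


def mini_cohort(n):
    return Cohort(make_cohort_frame([{} for _ in range(n)]))


class TestConfusionAt:
    def test_perfect_classifier(self):
        y = np.array([True, True, False, False, True, False])
        counts = confusion_at(mini_cohort(6), y, y)
        assert (counts.fp, counts.fn) == (0, 0)
        assert counts.tp == 3 and counts.tn == 3

    def test_inverted_classifier(self):
        y = np.array([True, False, True, False])
        counts = confusion_at(mini_cohort(4), ~y, y)
        assert (counts.tp, counts.tn) == (0, 0)

    def test_eight_record_hand_tally(self):
        classifier = np.array([1, 1, 1, 0, 0, 1, 0, 0], dtype=bool)
        outcome = np.array([1, 1, 0, 1, 0, 0, 0, 1], dtype=bool)
        counts = confusion_at(mini_cohort(8), classifier, outcome)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (2, 2, 2, 2)
        assert counts.n == 8

    def test_degenerate_outcome_errors(self):
        with pytest.raises(DegenerateOutcomeError):
            confusion_at(mini_cohort(4), np.array([1, 0, 1, 0], dtype=bool), np.ones(4, dtype=bool))

    def test_callable_classifier_supported(self, small_cohort):
        mask = confusion_at(
            small_cohort,
            lambda r: r.derived.whtr >= 0.48,
            lambda r: r.derived.whtr >= 0.50,
        )
        assert mask.n == len(small_cohort)


class TestEvaluateCutoff:
    def test_auc_is_mean_of_sens_and_spec(self):
        # sens 0.917, spec 0.744 -> AUC 0.8305 (reported to 3 dp as 0.830)
        counts = ConfusionCounts(tp=917, fn=83, tn=744, fp=256)
        ev = evaluate_cutoff(counts)
        assert ev.sens == pytest.approx(0.917)
        assert ev.spec == pytest.approx(0.744)
        assert ev.auc == pytest.approx(0.8305)
        assert ev.auc == pytest.approx((ev.sens + ev.spec) / 2)

    def test_perfect_and_chance_lines(self):
        perfect = evaluate_cutoff(ConfusionCounts(tp=10, fn=0, tn=10, fp=0))
        assert (perfect.auc, perfect.youden) == (1.0, 1.0)
        chance = evaluate_cutoff(ConfusionCounts(tp=5, fn=5, tn=5, fp=5))
        assert (chance.auc, chance.youden) == (0.5, 0.0)

    def test_youden_auc_identity_to_machine_precision(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, fn, tn, fp = rng.integers(1, 500, size=4)
            ev = evaluate_cutoff(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert ev.auc == (ev.sens + ev.spec) / 2
            assert ev.auc == pytest.approx((ev.youden + 1) / 2, abs=1e-15)
            assert 0.0 <= ev.auc <= 1.0

    def test_ci_formula_and_clipping(self):
        counts = ConfusionCounts(tp=917, fn=83, tn=744, fp=256)
        ev = evaluate_cutoff(counts)
        half = 1.96 * np.sqrt(0.917 * 0.083 / 4000 + 0.744 * 0.256 / 4000)
        assert ev.auc_ci == pytest.approx((0.8305 - half, 0.8305 + half))
        tight = evaluate_cutoff(ConfusionCounts(tp=3, fn=0, tn=3, fp=0))
        assert tight.auc_ci == (1.0, 1.0)


class TestStaticGrid:
    def test_default_grid_is_the_fifteen_hundredths(self):
        grid = static_grid()
        assert grid == [round(0.42 + 0.01 * i, 2) for i in range(15)]
        assert len(grid) == 15
        assert all(g == round(g, 2) for g in grid)  # exact hundredths, no drift

    def test_bad_grid_errors(self):
        with pytest.raises(WhtrError):
            static_grid(0.5, 0.4)

    def test_monotone_sens_spec_along_grid(self, growth_ref, bp_ref):
        cohort, _ = generate_cohort(
            SyntheticConfig(n=3000, seed=2, region="A", criteria="IDF"), growth_ref, bp_ref
        )
        evals = evaluate_static_grid(cohort, Criteria.IDF, 2, bp_ref)
        sens = [e.sens for e in evals]
        spec = [e.spec for e in evals]
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))

    def test_counts_match_brute_force_on_small_cohort(self, growth_ref, bp_ref):
        cohort, _ = generate_cohort(
            SyntheticConfig(n=50, seed=4, region="B", criteria="IDF"), growth_ref, bp_ref
        )
        from whtr_cutoffs.cutoffs import outcome_mask

        y = outcome_mask(cohort, Criteria.IDF, 2, bp_ref)
        if not (y.any() and (~y).any()):
            pytest.skip("degenerate draw")
        evals = evaluate_static_grid(cohort, Criteria.IDF, 2, bp_ref, outcome=y)
        whtr = cohort.df["whtr"].to_numpy()
        for ev in evals:
            pred = whtr >= ev.cutoff
            assert ev.counts.tp == int(np.sum(pred & y))
            assert ev.counts.tn == int(np.sum(~pred & ~y))

    def test_permuting_records_changes_nothing(self, growth_ref, bp_ref):
        cohort, _ = generate_cohort(
            SyntheticConfig(n=400, seed=8, region="A", criteria="IDF"), growth_ref, bp_ref
        )
        rng = np.random.default_rng(0)
        perm = cohort.subset(np.ones(len(cohort), dtype=bool))
        perm.df = perm.df.iloc[rng.permutation(len(cohort))].reset_index(drop=True)
        a = evaluate_static_grid(cohort, Criteria.IDF, 2, bp_ref)
        b = evaluate_static_grid(perm, Criteria.IDF, 2, bp_ref)
        assert [e.counts for e in a] == [e.counts for e in b]


class TestPercentileCandidates:
    def test_one_evaluation_per_candidate_and_monotone_sens(self, growth_ref, bp_ref):
        cohort, _ = generate_cohort(
            SyntheticConfig(n=4000, seed=3, region="A", criteria="IDF"), growth_ref, bp_ref
        )
        table = whtr_percentile_table(cohort, min_cell_n=10)
        evals = evaluate_percentile_candidates(cohort, table, criteria=Criteria.IDF, bp_ref=bp_ref)
        assert [e.cutoff for e in evals] == [75, 80, 85, 90, 95]
        sens = [e.sens for e in evals]
        assert all(a >= b for a, b in zip(sens, sens[1:]))

    def test_single_candidate_gives_single_evaluation(self, growth_ref, bp_ref):
        cohort, _ = generate_cohort(
            SyntheticConfig(n=2000, seed=3, region="A", criteria="IDF"), growth_ref, bp_ref
        )
        table = whtr_percentile_table(cohort, candidates=(85,), min_cell_n=10)
        evals = evaluate_percentile_candidates(
            cohort, table, candidates=(85,), criteria=Criteria.IDF, bp_ref=bp_ref
        )
        assert len(evals) == 1 and evals[0].kind == "percentile"


def _eval_with(youden, sens, cutoff):
    # construct counts realising the requested sens/spec (spec = youden+1-sens)
    spec = youden + 1.0 - sens
    n = 10_000
    tp = round(sens * n)
    tn = round(spec * n)
    return evaluate_cutoff(
        ConfusionCounts(tp=tp, fn=n - tp, tn=tn, fp=n - tn), cutoff=cutoff
    )


class TestSelectOptimal:
    def test_argmax_youden(self):
        evals = [_eval_with(y, 0.6, c) for y, c in [(0.2, 0.44), (0.5, 0.48), (0.3, 0.52)]]
        assert select_optimal(evals).cutoff == 0.48

    def test_tie_prefers_higher_sensitivity_then_lower_cutoff(self):
        tie_sens = [_eval_with(0.4, 0.5, 0.46), _eval_with(0.4, 0.9, 0.50)]
        assert select_optimal(tie_sens).cutoff == 0.50
        tie_all = [_eval_with(0.4, 0.7, 0.50), _eval_with(0.4, 0.7, 0.46)]
        assert select_optimal(tie_all).cutoff == 0.46

    def test_empty_list_errors(self):
        with pytest.raises(WhtrError):
            select_optimal([])

    @given(st.lists(st.tuples(
        st.integers(1, 200), st.integers(0, 200), st.integers(1, 200), st.integers(0, 200)
    ), min_size=1, max_size=12))
    def test_matches_exhaustive_scan(self, tuples):
        evals = [
            evaluate_cutoff(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp), cutoff=i / 100)
            for i, (tp, fn, tn, fp) in enumerate(tuples)
        ]
        best = select_optimal(evals)
        assert best.youden == max(e.youden for e in evals)


class TestConsolidate:
    def test_constant_group(self):
        out = consolidate({"a": 0.50, "b": 0.50, "c": 0.50}, {"a": "g", "b": "g", "c": "g"})
        assert out.values == {"g": 0.50}

    def test_median_by_sort(self):
        optima = dict(zip("abcde", [0.45, 0.46, 0.46, 0.46, 0.47]))
        out = consolidate(optima, {s: "g" for s in "abcde"})
        assert out.values == {"g": 0.46}
        row = out.dispersion.iloc[0]
        assert (row["min"], row["max"]) == (0.45, 0.47)

    def test_round_half_up(self):
        out = consolidate({"a": 0.45, "b": 0.46}, {"a": "g", "b": "g"})
        assert out.values == {"g": 0.46}  # median 0.455 rounds up

    def test_groups_are_independent(self):
        out = consolidate(
            {"a": 0.50, "b": 0.46}, {"a": "europe_usa", "b": "asia_africa_sa"}
        )
        assert out.values == {"europe_usa": 0.50, "asia_africa_sa": 0.46}

    def test_unassigned_stratum_errors(self):
        with pytest.raises(WhtrError):
            consolidate({"a": 0.50}, {})


class TestSensitivityK3:
    def test_k3_positives_nest_within_k2(self, growth_ref, bp_ref):
        from whtr_cutoffs.cutoffs import outcome_mask

        cohort, _ = generate_cohort(
            SyntheticConfig(n=5000, seed=13, region="A", criteria="IDF"), growth_ref, bp_ref
        )
        y2 = outcome_mask(cohort, Criteria.IDF, 2, bp_ref)
        y3 = outcome_mask(cohort, Criteria.IDF, 3, bp_ref)
        assert np.all(~y3 | y2)

    def test_no_triple_clustering_is_degenerate(self, small_cohort):
        with pytest.raises(DegenerateOutcomeError):
            evaluate_static_grid(small_cohort, Criteria.IDF, 3)

    def test_k3_optimum_near_k2_optimum(self, growth_ref, bp_ref):
        cohort, truth = generate_cohort(
            SyntheticConfig(n=20_000, seed=21, region="A", criteria="IDF"), growth_ref, bp_ref
        )
        best = {}
        for k in (2, 3):
            evals = evaluate_static_grid(cohort, Criteria.IDF, k, bp_ref)
            best[k] = select_optimal(evals).cutoff
        assert abs(best[3] - best[2]) <= 0.02 + 1e-9
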