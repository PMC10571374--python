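"""Leave-one-out wrapper marker selection."""

import numpy as np
import pytest

from crpopf.bayes import fit, predict_batch
from crpopf.cohort import Cohort, NON_PDAC, discretize_cohort
from crpopf.metrics import PerformanceMetrics, confusion, metrics_from_confusion
from crpopf.selection import (
    SelectionConfig,
    SelectionError,
    enumerate_combinations,
    leave_one_out_selection,
    loo_heldout_performance,
    per_size_report,
    resubstitution_estimate,
    select_best,
)
from crpopf.simulate import default_training_like_config, generate_cohort
from conftest import make_record


def _pm(sens, spec, f1=None):
    return PerformanceMetrics(sens, spec, None, None, f1)


class TestEnumeration:
    def test_counts(self):
        markers = [f"m{i:02d}" for i in range(14)]
        assert len(enumerate_combinations(markers, 1)) == 14
        assert len(enumerate_combinations(markers, 2)) == 91
        assert len(enumerate_combinations(["a", "b", "c"], 3)) == 1

    def test_sorted_deterministic(self):
        combos = enumerate_combinations(["c", "a", "b"], 2)
        assert combos == [("a", "b"), ("a", "c"), ("b", "c")]

    def test_out_of_range(self):
        with pytest.raises(SelectionError):
            enumerate_combinations(["a"], 2)
        with pytest.raises(SelectionError):
            enumerate_combinations(["a"], 0)


class TestSelectBest:
    def test_specificity_floor_applied(self):
        metrics = {("A",): _pm(0.9, 0.4), ("B",): _pm(0.8, 0.6)}
        assert select_best(metrics) == ("B",)

    def test_sensitivity_maximized_among_qualifying(self):
        metrics = {("A",): _pm(0.9, 0.6), ("B",): _pm(0.8, 0.9)}
        assert select_best(metrics) == ("A",)

    def test_tie_prefers_fewer_then_lexicographic(self):
        metrics = {("m1", "m2"): _pm(0.8, 0.8), ("m1",): _pm(0.8, 0.8)}
        assert select_best(metrics) == ("m1",)
        metrics = {("m2",): _pm(0.8, 0.8), ("m1",): _pm(0.8, 0.8)}
        assert select_best(metrics) == ("m1",)

    def test_fallback_to_f1_when_floor_unmet(self):
        metrics = {
            ("A",): _pm(0.9, 0.1, f1=0.4),
            ("B",): _pm(0.7, 0.2, f1=0.6),
        }
        assert select_best(metrics, specificity_floor=0.5) == ("B",)

    def test_max_f1_criterion(self):
        metrics = {("A",): _pm(0.9, 0.9, f1=0.5), ("B",): _pm(0.5, 0.5, f1=0.7)}
        assert select_best(metrics, criterion="max_f1") == ("B",)

    def test_empty_rejected(self):
        with pytest.raises(SelectionError):
            select_best({})


class TestResubstitution:
    def test_perfect_separator(self, separating_cohort):
        m = resubstitution_estimate(separating_cohort, ("mpd_index",), alpha=0.0)
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_constant_marker_balanced_classes_predicts_all_positive(self):
        records = tuple(
            make_record(i, mpd_index=0.5, cr_popf=i < 5) for i in range(10)
        )
        m = resubstitution_estimate(Cohort(records), ("mpd_index",), alpha=0.0)
        assert m.sensitivity == 1.0 and m.specificity == 0.0  # tie rule

    def test_eight_sample_style_fixture(self):
        # MPD index bins 0/1 reproduce the {3,1 / 1,3} count table
        records = tuple(
            make_record(i, mpd_index=idx, cr_popf=y)
            for i, (idx, y) in enumerate(
                [
                    (0.2, True), (0.2, True), (0.2, True), (0.5, True),
                    (0.2, False), (0.5, False), (0.5, False), (0.5, False),
                ]
            )
        )
        m = resubstitution_estimate(Cohort(records), ("mpd_index",), alpha=0.0)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(0.75)

    def test_single_class_rejected(self):
        records = tuple(make_record(i, cr_popf=True) for i in range(4))
        with pytest.raises(ValueError):
            resubstitution_estimate(Cohort(records), ("mpd_index",))


def _reference_loo(cohort, config):
    """Slow independent route: refit every (fold, combination) from scratch
    via the public fit/predict API."""
    names = config.candidates()
    combos = []
    for k in range(1, config.max_combo_size + 1):
        combos.extend(enumerate_combinations(names, k))
    labels = cohort.labels()
    selections = []
    for j in range(len(cohort.records)):
        sub = Cohort(
            cohort.records[:j] + cohort.records[j + 1 :], cohort.panel
        )
        sub_labels = labels[:j] + labels[j + 1 :]
        if not (any(sub_labels) and not all(sub_labels)):
            continue
        per_combo = {
            c: resubstitution_estimate(sub, c, alpha=config.smoothing_alpha)
            for c in combos
        }
        selections.append(
            select_best(per_combo, config.criterion, config.specificity_floor)
        )
    return selections


class TestLeaveOneOut:
    def test_matches_reference_implementation(self):
        cohort = generate_cohort(default_training_like_config(n=26, seed=42))
        config = SelectionConfig(
            max_combo_size=2,
            candidate_markers=("mpd_index", "bmi", "sex", "diabetes"),
        )
        result = leave_one_out_selection(cohort, config)
        reference = _reference_loo(cohort, config)
        assert [fs.selected_combination for fs in result.fold_selections] == reference

    def test_dominant_marker_wins_every_fold(self, separating_cohort):
        config = SelectionConfig(max_combo_size=2, smoothing_alpha=0.0)
        result = leave_one_out_selection(separating_cohort, config)
        assert result.winner == ("mpd_index",)
        assert result.tally[("mpd_index",)] == result.n_folds

    def test_tally_sums_to_executed_folds(self):
        cohort = generate_cohort(default_training_like_config(n=40, seed=7))
        result = leave_one_out_selection(
            cohort, SelectionConfig(candidate_markers=("mpd_index", "bmi", "age"))
        )
        assert sum(result.tally.values()) == result.n_folds
        assert result.n_folds + len(result.skipped_folds) == len(cohort)

    def test_deterministic(self):
        cohort = generate_cohort(default_training_like_config(n=30, seed=3))
        config = SelectionConfig(candidate_markers=("mpd_index", "bmi", "sex"))
        r1 = leave_one_out_selection(cohort, config)
        r2 = leave_one_out_selection(cohort, config)
        assert r1 == r2

    def test_degenerate_cohort_rejected(self):
        records = tuple(make_record(i, cr_popf=i == 0) for i in range(6))
        with pytest.raises(SelectionError):
            leave_one_out_selection(Cohort(records), SelectionConfig())

    def test_per_size_report_isolated_sizes(self, separating_cohort):
        config = SelectionConfig(max_combo_size=2, smoothing_alpha=0.0)
        by_size = per_size_report(separating_cohort, config)
        assert by_size[1].winner == ("mpd_index",)
        assert all(len(c) == 2 for c in by_size[2].tally)
        assert "mpd_index" in by_size[2].winner

    def test_heldout_diagnostic_perfect_separator(self, separating_cohort):
        cm, m = loo_heldout_performance(
            separating_cohort, ("mpd_index",), alpha=0.0
        )
        assert m.sensitivity == 1.0 and m.specificity == 1.0
        assert cm.total == len(separating_cohort)
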