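"""Leave-one-out wrapper selection of the optimal marker combination.

The procedure: for each of the N training samples in turn, hold that sample
out, and on the remaining N-1 sub-training samples evaluate *every* candidate
marker combination by fitting the discrete Bayes classifier and scoring its
re-substitution performance (classifying the same N-1 samples).  One
combination is selected per fold — either the one with maximal sensitivity
subject to a specificity floor (default 50%), or the one with maximal F1 —
and the combination selected most frequently across the N folds wins.  The
held-out sample itself never influences selection.

Two search modes are provided.  :func:`leave_one_out_selection` searches all
sizes 1..max_combo_size in a single run (size ties broken toward fewer
markers), which lets one call return a single-marker winner in one stratum
and a pair in another.  :func:`per_size_report` repeats the selection
separately for each combination size, the way size-by-size report tables are
built, and returns one result per size.

The whole procedure is deterministic: there is no randomness anywhere, and
all ties are broken by (fewer markers, lexicographic marker names).

Implementation note: within one combination, the sub-training set of a fold
is the full training table minus one sample, so the fitted classifier — and
hence the re-substitution metrics — depend only on the held-out sample's
(label, cell) pair.  Folds are therefore grouped by that pair, reducing the
N x (combinations) classifier fits to at most 2 x 2^k distinct fits per
combination with identical results.  :func:`resubstitution_estimate` is the
direct reference implementation of a single evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations as _iter_combinations
from math import inf
from typing import Mapping, Optional, Sequence

import numpy as np

from .bayes import fit, predict_batch
from .cohort import Cohort, discretize_cohort
from .metrics import (
    ConfusionMatrix,
    PerformanceMetrics,
    confusion,
    metrics_from_confusion,
)

__all__ = [
    "SelectionError",
    "SelectionConfig",
    "FoldSelection",
    "SelectionResult",
    "enumerate_combinations",
    "resubstitution_estimate",
    "select_best",
    "leave_one_out_selection",
    "per_size_report",
    "loo_heldout_performance",
]

logger = logging.getLogger(__name__)

MAX_SENS_CRITERION = "max_sensitivity_with_specificity_floor"
MAX_F1_CRITERION = "max_f1"

# candidate panel for stratified selection: the 14 markers minus diagnosis,
# which is the stratification variable rather than a classifier input
DEFAULT_CANDIDATES = (
    "age",
    "sex",
    "bmi",
    "vfa",
    "pni",
    "albumin",
    "parenchymal_thickness",
    "mpd_size",
    "mpd_index",
    "diabetes",
    "biliary_drainage",
    "conut",
    "sarcopenia",
)


class SelectionError(ValueError):
    """Invalid selection request (degenerate cohort, bad configuration)."""


@dataclass(frozen=True)
class SelectionConfig:
    """Configuration of the leave-one-out marker-selection procedure."""

    max_combo_size: int = 2
    criterion: str = MAX_SENS_CRITERION
    specificity_floor: float = 0.5
    smoothing_alpha: float = 1.0
    candidate_markers: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.max_combo_size < 1:
            raise SelectionError("max_combo_size must be >= 1")
        if not 0.0 <= self.specificity_floor <= 1.0:
            raise SelectionError("specificity_floor must be in [0, 1]")
        if self.criterion not in (MAX_SENS_CRITERION, MAX_F1_CRITERION):
            raise SelectionError(f"unknown criterion {self.criterion!r}")

    def candidates(self) -> tuple[str, ...]:
        return (
            tuple(self.candidate_markers)
            if self.candidate_markers is not None
            else DEFAULT_CANDIDATES
        )


@dataclass(frozen=True)
class FoldSelection:
    """The combination chosen in one leave-one-out fold."""

    held_out_id: str
    selected_combination: tuple[str, ...]
    criterion_value: float
    fallback: bool = False  # specificity floor unmet by every combination


@dataclass(frozen=True)
class SelectionResult:
    """Per-fold selections, their frequency tally, and the winner."""

    fold_selections: tuple[FoldSelection, ...]
    tally: Mapping[tuple[str, ...], int]
    winner: tuple[str, ...]
    skipped_folds: tuple[str, ...] = ()

    @property
    def n_folds(self) -> int:
        return len(self.fold_selections)


def enumerate_combinations(
    markers: Sequence[str], k: int
) -> list[tuple[str, ...]]:
    """All size-k marker subsets in deterministic lexicographic order."""
    if not 1 <= k <= len(markers):
        raise SelectionError(
            f"combination size {k} out of range for {len(markers)} markers"
        )
    return list(_iter_combinations(sorted(markers), k))


def resubstitution_estimate(
    subtraining: Cohort, combination: Sequence[str], alpha: float = 1.0
) -> PerformanceMetrics:
    """Fit on the sub-training set and score it on the same samples.

    This is the per-combination evaluation inside each leave-one-out fold:
    optimistic by construction, but exactly what the per-fold selection
    criterion consumes.
    """
    profiles = discretize_cohort(subtraining, list(combination))
    labels = subtraining.labels()
    clf = fit(profiles, labels, alpha=alpha)
    preds = predict_batch(clf, profiles)
    return metrics_from_confusion(confusion(preds, labels))


def _tie_key(combo: tuple[str, ...]) -> tuple:
    return (len(combo), combo)


def _argmax_metric(
    items: Sequence[tuple[tuple[str, ...], Optional[float]]]
) -> tuple[tuple[str, ...], float]:
    best_combo, best_val = None, -inf
    for combo, val in items:
        v = -inf if val is None else val
        if v > best_val or (v == best_val and _tie_key(combo) < _tie_key(best_combo)):
            best_combo, best_val = combo, v
    return best_combo, best_val


def select_best(
    per_combination_metrics: Mapping[tuple[str, ...], PerformanceMetrics],
    criterion: str = MAX_SENS_CRITERION,
    specificity_floor: float = 0.5,
) -> tuple[str, ...]:
    """Pick one combination from per-combination re-substitution metrics.

    Under the sensitivity criterion, the specificity floor is applied first;
    if no combination satisfies it the fold falls back to maximal F1 (logged).
    Ties always prefer fewer markers, then lexicographic marker names.
    """
    combo, _, _ = _select_best_detailed(
        per_combination_metrics, criterion, specificity_floor
    )
    return combo


def _select_best_detailed(
    per_combination_metrics: Mapping[tuple[str, ...], PerformanceMetrics],
    criterion: str,
    specificity_floor: float,
) -> tuple[tuple[str, ...], float, bool]:
    if not per_combination_metrics:
        raise SelectionError("no combinations were evaluated")
    items = sorted(per_combination_metrics.items(), key=lambda kv: _tie_key(kv[0]))
    if criterion == MAX_F1_CRITERION:
        combo, val = _argmax_metric([(c, m.f1) for c, m in items])
        return combo, val, False
    qualifying = [
        (c, m.sensitivity)
        for c, m in items
        if m.specificity is not None and m.specificity >= specificity_floor
    ]
    if qualifying:
        combo, val = _argmax_metric(qualifying)
        return combo, val, False
    combo, val = _argmax_metric([(c, m.f1) for c, m in items])
    return combo, val, True


# ---------------------------------------------------------------------------
# The leave-one-out loop
# ---------------------------------------------------------------------------


def _bin_matrix(cohort: Cohort, names: Sequence[str]) -> np.ndarray:
    profiles = discretize_cohort(cohort, names)
    return np.array([p.bins for p in profiles], dtype=np.int64)


def _subtraining_metrics(
    counts: np.ndarray, held_label: int, held_code: int, alpha: float
) -> PerformanceMetrics:
    """Re-substitution metrics on the training table minus one sample."""
    sub = counts.copy()
    sub[held_label, held_code] -= 1
    totals = sub.sum(axis=1)  # (n_neg, n_pos)
    n_cells = sub.shape[1]
    # maximum-posterior decision per cell, cross-multiplied (quotient-free)
    # so posterior ties resolve to positive exactly, as in bayes.predict
    lhs = totals[1] * (sub[1] + alpha) * (totals[0] + alpha * n_cells)
    rhs = totals[0] * (sub[0] + alpha) * (totals[1] + alpha * n_cells)
    decide_pos = lhs >= rhs
    tp = int(sub[1, decide_pos].sum())
    fn = int(sub[1, ~decide_pos].sum())
    fp = int(sub[0, decide_pos].sum())
    tn = int(sub[0, ~decide_pos].sum())
    return metrics_from_confusion(ConfusionMatrix(tp, fp, fn, tn))


def _run_loo(
    cohort: Cohort,
    config: SelectionConfig,
    sizes: Sequence[int],
) -> SelectionResult:
    names = config.candidates()
    bins = _bin_matrix(cohort, names)
    labels = np.array(cohort.labels(), dtype=bool)
    ids = [r.id for r in cohort.records]
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos < 2 or n_neg < 2:
        raise SelectionError(
            "leave-one-out selection needs at least 2 samples per class "
            f"(got {n_pos} positive, {n_neg} negative)"
        )
    name_to_col = {nm: i for i, nm in enumerate(names)}
    combos: list[tuple[str, ...]] = []
    for k in sizes:
        combos.extend(enumerate_combinations(names, k))

    alpha = config.smoothing_alpha
    y = labels.astype(np.int64)
    combo_codes: list[np.ndarray] = []
    combo_counts: list[np.ndarray] = []
    for combo in combos:
        cols = [name_to_col[nm] for nm in combo]
        weights = 1 << np.arange(len(cols))
        codes = bins[:, cols] @ weights
        counts = np.zeros((2, 1 << len(cols)), dtype=np.int64)
        np.add.at(counts, (y, codes), 1)
        combo_codes.append(codes)
        combo_counts.append(counts)

    caches: list[dict[tuple[int, int], PerformanceMetrics]] = [
        {} for _ in combos
    ]
    fold_selections: list[FoldSelection] = []
    skipped: list[str] = []
    for j in range(len(labels)):
        # a fold whose removal empties a class cannot fit any classifier
        if (labels[j] and n_pos == 1) or (not labels[j] and n_neg == 1):
            logger.warning("skipping degenerate fold for sample %s", ids[j])
            skipped.append(ids[j])
            continue
        per_combo: dict[tuple[str, ...], PerformanceMetrics] = {}
        for ci, combo in enumerate(combos):
            key = (int(y[j]), int(combo_codes[ci][j]))
            cache = caches[ci]
            if key not in cache:
                cache[key] = _subtraining_metrics(combo_counts[ci], *key, alpha)
            per_combo[combo] = cache[key]
        combo, value, fallback = _select_best_detailed(
            per_combo, config.criterion, config.specificity_floor
        )
        if fallback:
            logger.info(
                "fold %s: no combination met the specificity floor; used max F1",
                ids[j],
            )
        logger.debug(
            "fold %s: selected %s (criterion value %.4f%s)",
            ids[j],
            "+".join(combo),
            value,
            ", fallback" if fallback else "",
        )
        fold_selections.append(FoldSelection(ids[j], combo, value, fallback))

    if not fold_selections:
        raise SelectionError("every fold was degenerate; nothing was selected")
    tally: dict[tuple[str, ...], int] = {}
    for fs in fold_selections:
        tally[fs.selected_combination] = tally.get(fs.selected_combination, 0) + 1
    top = max(tally.values())
    winner = min((c for c, f in tally.items() if f == top), key=_tie_key)
    return SelectionResult(
        fold_selections=tuple(fold_selections),
        tally=tally,
        winner=winner,
        skipped_folds=tuple(skipped),
    )


def leave_one_out_selection(
    cohort: Cohort, config: SelectionConfig = SelectionConfig()
) -> SelectionResult:
    """Run the full procedure over all combination sizes 1..max_combo_size."""
    return _run_loo(cohort, config, range(1, config.max_combo_size + 1))


def per_size_report(
    cohort: Cohort, config: SelectionConfig = SelectionConfig()
) -> dict[int, SelectionResult]:
    """Repeat the selection separately for each combination size.

    Mirrors building a size-by-size report table: one independent selection
    run per size, so single markers and pairs never compete in one tally.
    """
    return {
        k: _run_loo(cohort, config, [k])
        for k in range(1, config.max_combo_size + 1)
    }


def loo_heldout_performance(
    cohort: Cohort, combination: Sequence[str], alpha: float = 1.0
) -> tuple[ConfusionMatrix, PerformanceMetrics]:
    """Leave-one-out *held-out* performance of one fixed combination.

    Unlike the re-substitution metrics used inside selection, each sample is
    classified by a model fitted without it; this is the honest diagnostic
    for how optimistic the selected combination's training metrics are.
    """
    profiles = discretize_cohort(cohort, list(combination))
    labels = cohort.labels()
    preds: list[bool] = []
    kept: list[bool] = []
    for j in range(len(labels)):
        sub_profiles = profiles[:j] + profiles[j + 1 :]
        sub_labels = labels[:j] + labels[j + 1 :]
        if not (any(sub_labels) and not all(sub_labels)):
            continue
        clf = fit(sub_profiles, sub_labels, alpha=alpha)
        preds.append(predict_batch(clf, [profiles[j]])[0])
        kept.append(labels[j])
    cm = confusion(preds, kept)
    return cm, metrics_from_confusion(cm)
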