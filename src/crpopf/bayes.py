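"""Discrete Bayes classifier over cut-off-dichotomized marker cells.

With k binary markers a patient falls into one of 2^k cells.  The classifier
estimates the prior of each outcome class (CR-POPF present/absent) and the
class-conditional probability of each cell from training counts, optionally
Laplace-smoothed, and classifies by maximum posterior:

    P(class | cell)  proportional to  P(class) * P(cell | class)

with P(cell | class) = (count + alpha) / (n_class + alpha * 2^k).

This is a *joint-cell* estimate, not a naive-Bayes factorization: with k <= 3
markers the full table has at most 8 cells and is well supported at clinical
training sizes.  A naive-Bayes (per-marker independence) variant is available
via ``independent=True`` for comparison only.

Class indexing convention throughout: index 0 = CR-POPF absent (negative),
index 1 = CR-POPF present (positive).  Ties in the posterior predict
positive — the model is designed to fail toward sensitivity, since a missed
fistula is costlier than a false alarm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import DiscretizedProfile

__all__ = [
    "ClassifierError",
    "FittingError",
    "FittedClassifier",
    "fit",
    "posterior",
    "predict",
    "predict_batch",
    "cell_code",
]


class ClassifierError(ValueError):
    """Classifier misuse (e.g. marker mismatch between fit and predict)."""


class FittingError(ClassifierError):
    """Training data cannot support a fit (e.g. a class has no samples)."""


def cell_code(bins: Sequence[int]) -> int:
    """Map a bin vector to its cell index (marker i contributes bit i)."""
    code = 0
    for i, b in enumerate(bins):
        code |= int(b) << i
    return code


@dataclass(frozen=True)
class FittedClassifier:
    """Per-cell class counts, priors and smoothing of a fitted classifier.

    ``counts`` has shape (2, 2^k): row 0 holds per-cell counts among
    CR-POPF-negative training samples, row 1 among positives.  Cells never
    seen in training have count 0.
    """

    marker_names: tuple[str, ...]
    counts: np.ndarray
    priors: np.ndarray
    alpha: float
    n_train: int
    uniform_priors: bool = False
    independent: bool = False
    # marginal per-marker "at-or-above-cutoff" counts, shape (2, k); only
    # used when independent=True
    marginal_counts: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def class_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def cell_likelihoods(self) -> np.ndarray:
        """P(cell | class), shape (2, 2^k)."""
        if self.independent:
            return _independent_cell_likelihoods(
                self.marginal_counts, self.class_totals(), self.alpha, len(self.marker_names)
            )
        totals = self.class_totals()[:, None]
        return (self.counts + self.alpha) / (totals + self.alpha * self.n_cells)


def _independent_cell_likelihoods(
    marginal: np.ndarray, totals: np.ndarray, alpha: float, k: int
) -> np.ndarray:
    p_one = (marginal + alpha) / (totals[:, None] + 2 * alpha)  # (2, k)
    cells = np.arange(2**k)
    bits = (cells[:, None] >> np.arange(k)) & 1  # (C, k)
    like = np.ones((2, 2**k))
    for c in (0, 1):
        like[c] = np.prod(np.where(bits == 1, p_one[c], 1 - p_one[c]), axis=1)
    return like


def fit(
    profiles: Sequence[DiscretizedProfile],
    labels: Sequence[bool],
    alpha: float = 1.0,
    uniform_priors: bool = False,
    independent: bool = False,
) -> FittedClassifier:
    """Fit the classifier from discretized profiles and CR-POPF labels.

    Parameters
    ----------
    alpha
        Laplace smoothing pseudo-count added to every (cell, class) pair;
        ``alpha=0`` gives maximum-likelihood estimates.
    uniform_priors
        Use 0.5/0.5 priors instead of empirical class frequencies.
    independent
        Fit the naive-Bayes factorized variant instead of joint cells.
    """
    if len(profiles) != len(labels):
        raise FittingError("profiles and labels must have equal length")
    if not profiles:
        raise FittingError("cannot fit on an empty training set")
    if alpha < 0:
        raise FittingError("smoothing alpha must be non-negative")
    names = profiles[0].marker_names
    k = len(names)
    counts = np.zeros((2, 2**k), dtype=np.int64)
    marginal = np.zeros((2, k), dtype=np.int64) if k else np.zeros((2, 0), dtype=np.int64)
    for p, y in zip(profiles, labels):
        if p.marker_names != names:
            raise FittingError(
                f"inconsistent marker lists: {p.marker_names} vs {names}"
            )
        c = int(bool(y))
        counts[c, cell_code(p.bins)] += 1
        if k:
            marginal[c] += np.asarray(p.bins, dtype=np.int64)
    totals = counts.sum(axis=1)
    if totals[0] == 0 or totals[1] == 0:
        raise FittingError(
            "both outcome classes must be present in the training set "
            f"(got {totals[1]} positive, {totals[0]} negative)"
        )
    priors = (
        np.array([0.5, 0.5]) if uniform_priors else totals / totals.sum()
    )
    return FittedClassifier(
        marker_names=names,
        counts=counts,
        priors=priors,
        alpha=float(alpha),
        n_train=int(totals.sum()),
        uniform_priors=uniform_priors,
        independent=independent,
        marginal_counts=marginal if independent else None,
    )


def _check_profile(clf: FittedClassifier, profile: DiscretizedProfile) -> int:
    if profile.marker_names != clf.marker_names:
        raise ClassifierError(
            f"profile markers {profile.marker_names} do not match classifier "
            f"markers {clf.marker_names}"
        )
    return cell_code(profile.bins)


def posterior(clf: FittedClassifier, profile: DiscretizedProfile) -> np.ndarray:
    """Posterior class probabilities [P(negative|cell), P(positive|cell)].

    If both prior-weighted likelihoods vanish (possible only at alpha=0 for a
    cell unseen in training), the priors are returned.
    """
    code = _check_profile(clf, profile)
    numer = clf.priors * clf.cell_likelihoods()[:, code]
    total = numer.sum()
    if total == 0:
        return clf.priors.copy()
    return numer / total


def predict(clf: FittedClassifier, profile: DiscretizedProfile) -> bool:
    """Maximum-posterior decision; a tie predicts CR-POPF positive.

    The comparison prior(+)*P(cell|+) >= prior(-)*P(cell|-) is evaluated in
    cross-multiplied form — products of counts, never quotients — so exact
    posterior ties (common at alpha=0) resolve to positive deterministically
    instead of depending on float round-off.
    """
    code = _check_profile(clf, profile)
    if clf.independent:
        post = posterior(clf, profile)
        return bool(post[1] >= post[0])
    n0, n1 = (int(t) for t in clf.class_totals())
    c0, c1 = int(clf.counts[0, code]), int(clf.counts[1, code])
    a, n_cells = clf.alpha, clf.n_cells
    w0, w1 = (1, 1) if clf.uniform_priors else (n0, n1)
    lhs = w1 * (c1 + a) * (n0 + a * n_cells)
    rhs = w0 * (c0 + a) * (n1 + a * n_cells)
    if lhs == 0 and rhs == 0:  # cell unseen in training at alpha=0
        return bool(clf.priors[1] >= clf.priors[0])
    return bool(lhs >= rhs)


def predict_batch(
    clf: FittedClassifier, profiles: Sequence[DiscretizedProfile]
) -> list[bool]:
    """Elementwise :func:`predict`, preserving order."""
    return [predict(clf, p) for p in profiles]
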