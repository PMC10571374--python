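"""The final diagnosis-stratified CR-POPF prediction model.

Patients are routed by preoperative diagnosis: PDAC patients are classified
by a discrete Bayes submodel over the MPD index alone (cut-off 0.3),
non-PDAC patients by a submodel over MPD index and BMI (cut-offs 0.3 and
25 kg/m^2).  The marker sets and cut-offs are fixed — they are the published
model — but the *risk direction* in every cell is learned from the training
cohort, never hardcoded; a discovery pathway that reruns marker selection
first is available via :func:`discover_model`.

Because each submodel has at most four cells, the whole model is a finite
decision table (:func:`decision_table`), which is also how it is serialized.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .bayes import FittedClassifier, fit, posterior, predict
from .cohort import (
    NON_PDAC,
    PDAC,
    Cohort,
    CohortError,
    DiscretizedProfile,
    MarkerDefinition,
    PatientRecord,
    discretize_record,
    stratify_by_diagnosis,
)
from .metrics import (
    ConfusionMatrix,
    PerformanceMetrics,
    confusion,
    metrics_from_confusion,
    pool_confusions,
)
from .selection import SelectionConfig, leave_one_out_selection

__all__ = [
    "ModelError",
    "StratifiedPredictionModel",
    "EvaluationReport",
    "PDAC_MARKERS",
    "NONPDAC_MARKERS",
    "build_final_model",
    "discover_model",
    "predict_patient",
    "evaluate_model",
    "decision_table",
    "model_to_json",
    "model_from_json",
    "save_model",
    "load_model",
]


class ModelError(ValueError):
    """The stratified model cannot be built or applied as requested."""


PDAC_MARKERS = ("mpd_index",)
NONPDAC_MARKERS = ("mpd_index", "bmi")

_SUBMODEL_PANELS = {
    PDAC: (MarkerDefinition("mpd_index", "continuous", 0.3),),
    NON_PDAC: (
        MarkerDefinition("mpd_index", "continuous", 0.3),
        MarkerDefinition("bmi", "continuous", 25.0),
    ),
}


@dataclass(frozen=True)
class StratifiedPredictionModel:
    """Two fitted submodels plus the cut-offs used to discretize inputs."""

    pdac_submodel: FittedClassifier
    nonpdac_submodel: FittedClassifier

    def __post_init__(self) -> None:
        if self.pdac_submodel.marker_names != PDAC_MARKERS:
            raise ModelError(
                f"PDAC submodel must use markers {PDAC_MARKERS}, "
                f"got {self.pdac_submodel.marker_names}"
            )
        if self.nonpdac_submodel.marker_names != NONPDAC_MARKERS:
            raise ModelError(
                f"non-PDAC submodel must use markers {NONPDAC_MARKERS}, "
                f"got {self.nonpdac_submodel.marker_names}"
            )

    def submodel(self, diagnosis: str) -> FittedClassifier:
        return self.pdac_submodel if diagnosis == PDAC else self.nonpdac_submodel


def _fit_stratum(cohort: Cohort, stratum: str, alpha: float) -> FittedClassifier:
    if not cohort.records:
        raise ModelError(f"training cohort has no {stratum} records")
    panel = _SUBMODEL_PANELS[stratum]
    profiles = [discretize_record(r, panel) for r in cohort.records]
    try:
        return fit(profiles, cohort.labels(), alpha=alpha)
    except ValueError as e:
        raise ModelError(f"{stratum} stratum: {e}") from e


def build_final_model(
    training: Cohort, alpha: float = 1.0
) -> StratifiedPredictionModel:
    """Fit both submodels on a labeled training cohort.

    The marker sets are fixed (MPD index for PDAC; MPD index + BMI for
    non-PDAC); only the per-cell counts — and hence the risk direction —
    come from the data.
    """
    pdac, non = stratify_by_diagnosis(training)
    return StratifiedPredictionModel(
        pdac_submodel=_fit_stratum(pdac, PDAC, alpha),
        nonpdac_submodel=_fit_stratum(non, NON_PDAC, alpha),
    )


def discover_model(
    training: Cohort,
    selection_config: Optional[SelectionConfig] = None,
    alpha: float = 1.0,
) -> tuple[StratifiedPredictionModel, dict[str, tuple[str, ...]]]:
    """Rerun marker selection per stratum, then fit the final model.

    Returns the fitted model and the per-stratum winning combinations.  The
    model itself is only built when selection re-discovers the published
    marker sets; otherwise a :class:`ModelError` reports what was selected
    instead, since the fixed-architecture model would not represent the
    discovered combination.
    """
    if selection_config is None:
        selection_config = SelectionConfig(max_combo_size=2, smoothing_alpha=alpha)
    pdac, non = stratify_by_diagnosis(training)
    winners = {
        PDAC: leave_one_out_selection(pdac, selection_config).winner,
        NON_PDAC: leave_one_out_selection(non, selection_config).winner,
    }
    if winners[PDAC] != tuple(sorted(PDAC_MARKERS)) or winners[NON_PDAC] != tuple(
        sorted(NONPDAC_MARKERS)
    ):
        raise ModelError(
            f"selection discovered {winners}, not the fixed model architecture"
        )
    return build_final_model(training, alpha=alpha), winners


def predict_patient(
    model: StratifiedPredictionModel, record: PatientRecord
) -> tuple[bool, float]:
    """Route a patient by diagnosis and return (decision, posterior of CR-POPF)."""
    panel = _SUBMODEL_PANELS[record.diagnosis]
    profile = discretize_record(record, panel)
    clf = model.submodel(record.diagnosis)
    post = posterior(clf, profile)
    return predict(clf, profile), float(post[1])


@dataclass(frozen=True)
class EvaluationReport:
    """Per-stratum and pooled confusion matrices and metrics."""

    confusions: dict[str, ConfusionMatrix]
    metrics: dict[str, PerformanceMetrics]
    pooled_confusion: ConfusionMatrix
    pooled_metrics: PerformanceMetrics


def evaluate_model(
    model: StratifiedPredictionModel, cohort: Cohort
) -> EvaluationReport:
    """Evaluate the model on a labeled cohort, per stratum and pooled."""
    pdac, non = stratify_by_diagnosis(cohort)
    confusions: dict[str, ConfusionMatrix] = {}
    metrics: dict[str, PerformanceMetrics] = {}
    for stratum, sub in ((PDAC, pdac), (NON_PDAC, non)):
        if not sub.records:
            warnings.warn(f"no {stratum} records to evaluate; stratum omitted")
            continue
        preds = [predict_patient(model, r)[0] for r in sub.records]
        cm = confusion(preds, sub.labels())
        confusions[stratum] = cm
        metrics[stratum] = metrics_from_confusion(cm)
    if not confusions:
        raise ModelError("cohort has no records in either stratum")
    pooled = pool_confusions(list(confusions.values()))
    return EvaluationReport(
        confusions=confusions,
        metrics=metrics,
        pooled_confusion=pooled,
        pooled_metrics=metrics_from_confusion(pooled),
    )


def decision_table(model: StratifiedPredictionModel) -> list[dict]:
    """The model as an explicit lookup table: one row per (stratum, cell).

    Two rows for PDAC (MPD index below/at-or-above 0.3) and four for
    non-PDAC (MPD index x BMI bins), each with the decision and the
    posterior probability of CR-POPF.
    """
    rows = []
    for stratum, markers in ((PDAC, PDAC_MARKERS), (NON_PDAC, NONPDAC_MARKERS)):
        clf = model.submodel(stratum)
        k = len(markers)
        for code in range(2**k):
            bins = tuple((code >> i) & 1 for i in range(k))
            profile = DiscretizedProfile(markers, bins)
            post = posterior(clf, profile)
            rows.append(
                {
                    "stratum": stratum,
                    "cell": dict(zip(markers, bins)),
                    "decision": predict(clf, profile),
                    "posterior_cr_popf": float(post[1]),
                }
            )
    return rows


# ---------------------------------------------------------------------------
# Serialization (counts kept exact so the model reconstructs bit-for-bit)
# ---------------------------------------------------------------------------


def _clf_to_dict(clf: FittedClassifier, panel: Sequence[MarkerDefinition]) -> dict:
    return {
        "marker_names": list(clf.marker_names),
        "cutoffs": {m.name: m.cutoff for m in panel},
        "counts": clf.counts.tolist(),
        "priors": clf.priors.tolist(),
        "alpha": clf.alpha,
        "n_train": clf.n_train,
    }


def _clf_from_dict(d: dict) -> FittedClassifier:
    return FittedClassifier(
        marker_names=tuple(d["marker_names"]),
        counts=np.array(d["counts"], dtype=np.int64),
        priors=np.array(d["priors"], dtype=float),
        alpha=float(d["alpha"]),
        n_train=int(d["n_train"]),
    )


def model_to_json(model: StratifiedPredictionModel) -> str:
    payload = {
        "format": "crpopf-stratified-model",
        "version": 1,
        "pdac": _clf_to_dict(model.pdac_submodel, _SUBMODEL_PANELS[PDAC]),
        "non_pdac": _clf_to_dict(model.nonpdac_submodel, _SUBMODEL_PANELS[NON_PDAC]),
        "decision_table": [
            {**row, "decision": bool(row["decision"])}
            for row in decision_table(model)
        ],
    }
    return json.dumps(payload, indent=2)


def model_from_json(text: str) -> StratifiedPredictionModel:
    try:
        payload = json.loads(text)
        if payload.get("format") != "crpopf-stratified-model":
            raise ModelError("not a crpopf stratified-model file")
        return StratifiedPredictionModel(
            pdac_submodel=_clf_from_dict(payload["pdac"]),
            nonpdac_submodel=_clf_from_dict(payload["non_pdac"]),
        )
    except (KeyError, TypeError, json.JSONDecodeError) as e:
        raise ModelError(f"malformed model file: {e}") from e


def save_model(model: StratifiedPredictionModel, path: str | Path) -> None:
    Path(path).write_text(model_to_json(model))


def load_model(path: str | Path) -> StratifiedPredictionModel:
    return model_from_json(Path(path).read_text())
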