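"""End-to-end orchestration: split -> fit reference -> score -> features ->
train -> evaluate.

This is the programmatic equivalent of the ``run-all`` CLI command and the
path exercised by the full-pipeline tests: given a cohort (beta matrix,
sample sheet, region map), it assigns the stratified split, fits the age/sex
reference model on training controls, scores every sample, builds the
feature matrices, trains the bagged weighted ensemble, and evaluates on the
held-out test set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .ensemble import PredictionResult, TrainedEnsemble, predict, train_ensemble
from .evaluation import EvaluationReport, evaluate_predictions
from .features import FeatureMatrix, FeatureSelectionState, build_features, split_train_test
from .io import BetaMatrix, PipelineConfig, RegionSet, SampleRecord
from .reference import ReferenceModel, fit_reference_model
from .scoring import ZScorePanel, compute_z_panel

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Artifacts of one full pipeline run."""

    samples: list[SampleRecord]
    reference: ReferenceModel
    panel: ZScorePanel
    train_features: FeatureMatrix
    test_features: FeatureMatrix
    selection_state: FeatureSelectionState
    ensemble: TrainedEnsemble
    predictions: PredictionResult
    report: EvaluationReport


def run_pipeline(
    beta: BetaMatrix,
    samples: Sequence[SampleRecord],
    regions: RegionSet,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the whole classification pipeline on one cohort.

    Samples without split assignments receive a stratified split first; the
    reference model uses training controls only, and all feature selection is
    fitted on the training set.
    """
    config = config or PipelineConfig()
    samples = list(samples)
    if all(s.split == "unassigned" for s in samples):
        samples = split_train_test(samples, config.train_fraction, config.seed)
    reference = fit_reference_model(beta, samples, epsilon=config.logit_epsilon)
    panel = compute_z_panel(
        beta, samples, reference, config.regularization_weight, config.logit_epsilon
    )
    train_features, test_features, state = build_features(panel, samples, regions, config)
    train_labels = [s.class_label for s in samples if s.split == "train"]
    ensemble = train_ensemble(
        train_features.values,
        train_labels,
        k=config.bag_folds,
        seed=config.seed,
    )
    predictions = predict(ensemble, test_features.values)
    label_by_id = {s.sample_id: s.class_label for s in samples}
    true_labels = [label_by_id[sid] for sid in predictions.sample_ids]
    report = evaluate_predictions(true_labels, predictions.predicted, ensemble.class_order)
    return PipelineResult(
        samples=samples,
        reference=reference,
        panel=panel,
        train_features=train_features,
        test_features=test_features,
        selection_state=state,
        ensemble=ensemble,
        predictions=predictions,
        report=report,
    )
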