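"""End-to-end experiment driver: split, extract, select, stack, evaluate.

This is the programmatic face of the workflow the CLI wires together:
feature extraction over all transcripts, an mRMR ranking computed on the
training split only (bin edges included), stacking-model training on the
selected columns, and held-out evaluation of both the stacked model and
each fold-averaged base learner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .seqio import AnnotationIntervalSet, TranscriptRecord
from .selection import (
    EncoderConfig,
    FeatureMatrix,
    MRMRRanking,
    assemble_features,
    mrmr_rank,
)
from .stacking import (
    StackedModel,
    StackingConfig,
    base_meta_features,
    evaluate,
    fit_stacked,
    predict_stacked,
)

DEFAULT_SELECTION_DIMENSION = 110


@dataclass
class ExperimentResult:
    metrics: dict[str, float]  # stacked-model test metrics
    base_metrics: dict[str, dict[str, float]]  # per base learner
    ranking: MRMRRanking
    selected_features: list[str]
    model: StackedModel
    n_train: int
    n_test: int


def split_matrix(
    matrix: FeatureMatrix, test_size: float = 0.25, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    idx = np.arange(len(matrix.ids))
    tr, _ = train_test_split(
        idx, test_size=test_size, stratify=matrix.labels, random_state=seed
    )
    mask = np.zeros(len(idx), dtype=bool)
    mask[tr] = True
    return matrix.rows(mask), matrix.rows(~mask)


def run_experiment(
    records: Sequence[TranscriptRecord],
    alu: AnnotationIntervalSet | None = None,
    dimension: int = DEFAULT_SELECTION_DIMENSION,
    seed: int = 0,
    encoder_config: EncoderConfig | None = None,
    stacking_config: StackingConfig | None = None,
    test_size: float = 0.25,
    criterion: str = "MID",
    bins: int = 10,
) -> ExperimentResult:
    """Full train/test run of the classification pipeline on labeled records."""
    matrix = assemble_features(records, alu, encoder_config)
    train, test = split_matrix(matrix, test_size=test_size, seed=seed)
    ranking = mrmr_rank(train, m=dimension, criterion=criterion, bins=bins)  # type: ignore[arg-type]
    names = ranking.top(dimension)
    train_sel, test_sel = train.subset(names), test.subset(names)
    model = fit_stacked(train_sel, stacking_config, seed=seed)

    probs, calls = predict_stacked(model, test_sel)
    metrics = evaluate(calls, test_sel.labels, probs)

    base_metrics: dict[str, dict[str, float]] = {}
    meta_feats = base_meta_features(model, test_sel)
    for b, name in enumerate(model.base_names):
        base_calls = (meta_feats[:, b] >= model.config.threshold).astype(int)
        base_metrics[name] = evaluate(base_calls, test_sel.labels)
    return ExperimentResult(
        metrics=metrics,
        base_metrics=base_metrics,
        ranking=ranking,
        selected_features=names,
        model=model,
        n_train=len(train_sel.ids),
        n_test=len(test_sel.ids),
    )
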