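"""End-to-end orchestration: series -> labels -> features -> batches -> model.

This glue module wires the stage modules together the way the command-line
interface and the benchmark scripts use them: elbow-label the raw series,
split at the individual level (an outer train/test split plus an inner
train/validation split of the training individuals for early stopping and
grid search), fit the z-scaler on the training individuals only, build padded
batches and train or predict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .features import build_feature_matrix
from .io import IndividualSeries, ZScaleParams, apply_zscale, fit_zscale
from .labeler import RobustScaleParams, WeaningLabel, label_individuals
from .nn.model import (
    ModelConfig,
    TrainedModel,
    build_model,
    mc_dropout_predict,
    predictions_to_frame,
    train,
)
from .sequences import PaddedBatch, pad_and_mask, split_individuals

logger = logging.getLogger(__name__)


@dataclass
class PreparedData:
    """Everything downstream of preprocessing, ready for training."""

    train_batch: PaddedBatch
    val_batch: PaddedBatch
    test_batch: PaddedBatch
    zscale: ZScaleParams
    robust_scale: RobustScaleParams
    labels: list[WeaningLabel]
    label_failures: list[tuple[str, str]] = field(default_factory=list)
    train_ids: list[str] = field(default_factory=list)
    val_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)


def prepare(
    series: Sequence[IndividualSeries],
    train_frac: float = 0.8,
    seed: int = 0,
    global_scaling: bool = False,
    min_range: float = 0.3,
    t_max: int | None = None,
) -> PreparedData:
    """Label, split, scale and batch a collection of filtered series.

    The outer split reserves ``1 - train_frac`` of individuals for testing;
    the training individuals are split again 80/20 into the actual training
    set and the early-stopping/grid-search validation set.  With
    ``global_scaling`` the z-scaler is fit on the whole dataset (strict
    replication mode) instead of the training split only.
    """
    labels, robust, failures = label_individuals(series, min_range=min_range)
    labelled_ids = {l.sample_id for l in labels}
    series = [s for s in series if s.sample_id in labelled_ids]
    by_id = {s.sample_id: s for s in series}
    label_by_id = {l.sample_id: l.scaled_value for l in labels}

    train_ids, test_ids = split_individuals(sorted(by_id), train_frac, seed)
    inner_train, val_ids = split_individuals(train_ids, 0.8, seed + 1)

    fit_on = series if global_scaling else [by_id[i] for i in train_ids]
    zparams = fit_zscale(fit_on)
    scaled = {s.sample_id: m for s, m in zip(series, apply_zscale(series, zparams))}

    if t_max is None:
        t_max = max(len(by_id[i]) for i in by_id)

    def batch(ids: list[str]) -> PaddedBatch:
        mats = [build_feature_matrix(scaled[i]) for i in ids]
        return pad_and_mask(mats, t_max=t_max, labels=label_by_id)

    return PreparedData(
        train_batch=batch(inner_train),
        val_batch=batch(val_ids),
        test_batch=batch(test_ids),
        zscale=zparams,
        robust_scale=robust,
        labels=labels,
        label_failures=failures,
        train_ids=inner_train,
        val_ids=val_ids,
        test_ids=test_ids,
    )


@dataclass
class ExperimentResult:
    model: TrainedModel
    predictions: pd.DataFrame  # per test individual
    prepared: PreparedData


def run_experiment(
    series: Sequence[IndividualSeries],
    config: ModelConfig | None = None,
    truth: pd.DataFrame | None = None,
    train_frac: float = 0.8,
    seed: int = 0,
    n_passes: int = 100,
    global_scaling: bool = False,
) -> ExperimentResult:
    """Train on labelled series and MC-dropout predict the held-out individuals.

    The returned prediction table has one row per test individual with the
    elbow label (years), the MC-dropout mean/sd/interval, tooth type and
    maximum sampled age; when a ``truth`` table (sample_id, completion_age)
    is supplied, the true completion age is joined in as well.
    """
    config = config or ModelConfig(seed=seed)
    prep = prepare(series, train_frac=train_frac, seed=seed,
                   global_scaling=global_scaling)
    net = build_model(config, prep.train_batch.t_max)
    model = train(net, prep.train_batch, prep.val_batch, config,
                  zscale=prep.zscale, robust_scale=prep.robust_scale)
    results = mc_dropout_predict(model, prep.test_batch, n_passes=n_passes,
                                 seed=config.seed + 2)
    df = predictions_to_frame(results)
    label_age = {l.sample_id: l.elbow_age for l in prep.labels}
    df["elbow_age"] = [label_age[s] for s in df["sample_id"]]
    df["tooth_type"] = prep.test_batch.tooth_types
    df["max_age"] = prep.test_batch.max_ages
    if truth is not None:
        df = df.merge(truth[["sample_id", "completion_age"]], on="sample_id", how="left")
    return ExperimentResult(model=model, predictions=df, prepared=prep)


def heldout_metrics(predictions: pd.DataFrame, reference: str = "elbow_age") -> dict:
    """RMSE / MAE / R^2 of the MC-dropout means against a reference column."""
    from .evaluate import mae, r2, rmse

    y = predictions[reference].to_numpy(dtype=float)
    p = predictions["mean_age"].to_numpy(dtype=float)
    return {"rmse": rmse(y, p), "mae": mae(y, p), "r2": r2(y, p), "n": len(predictions)}
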