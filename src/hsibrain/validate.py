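"""Stratified sampling, nested cross-validation and the two experiments.

Model selection is a double 5-fold cross-validation: an outer stratified
split isolates a test fold; the remaining 80% is re-stratified into five
sub-folds, and the inner loop trains five candidate models (four
calibration sub-folds, one validation sub-fold).  The inner candidate with
the best validation OACC predicts the isolated outer test fold; the outer
fold with the best test OACC supplies the final model.  Exactly 25 models
are trained per double CV.

Two evaluation designs sit on top:

* Experiment A (intra-patient): every image contributes 80% of its labeled
  pixels to training; an extra outer loop over the five per-image fold
  groupings (the same grouping index for every image) selects the best 80%
  before the double CV runs.  Per-image metrics are reported both on the
  held-out 20% folds and on full-image predictions.
* Experiment B (inter-patient): leave-one-image-out; the model selected by
  double CV on the pooled remaining images classifies the entire held-out
  image.  This is the clinically relevant design: the test image is never
  seen during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .classify import (ClassificationMap, LabeledDataset, ModelSpec,
                       TrainedModel, build_dataset, predict_image, train)
from .labeling import GroundTruthMap
from .metrics import MetricReport, confusion, oacc
from .preprocess import HyperCube

K_FOLDS = 5


def _derive_seed(seed: int, *idx: int) -> int:
    """Fixed-offset seed derivation, always in [0, 2^31)."""
    h = int(seed) % (2**31)
    for v in idx:
        h = (h * 1000003 + int(v) + 12345) % (2**31)
    return h


@dataclass
class FoldAssignment:
    """Per-sample fold ids in 1..k with per-class per-fold counts."""

    fold: np.ndarray
    k: int
    seed: int
    stratification: dict = field(default_factory=dict)

    def test_indices(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.fold == f)

    def train_indices(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.fold != f)


def stratified_kfold(labels: np.ndarray, k: int = K_FOLDS,
                     seed: int = 0) -> FoldAssignment:
    """Per-class shuffle then round-robin assignment to ``k`` folds.

    Guarantees per-class fold counts differ by at most one.  A class with
    fewer than ``k`` samples is rejected by name: it cannot populate every
    fold.
    """
    labels = np.asarray(labels)
    fold = np.zeros(labels.shape[0], dtype=np.int64)
    rng = np.random.default_rng(seed)
    strat: dict = {}
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls} has only {idx.size} samples; need >= {k} "
                f"for {k}-fold stratification")
        perm = rng.permutation(idx)
        fold[perm] = np.arange(perm.size) % k + 1
        strat[int(cls)] = {f: int(np.count_nonzero(fold[idx] == f))
                           for f in range(1, k + 1)}
    return FoldAssignment(fold=fold, k=k, seed=seed, stratification=strat)


@dataclass
class CVReport:
    """Outcome of one double cross-validation."""

    per_outer: list            # dicts: fold, inner_selected, val_oacc, test_oacc
    winner_outer: int
    winner_model: TrainedModel
    models_trained: int
    outer_folds: FoldAssignment

    @property
    def winner_test_oacc(self) -> float:
        return self.per_outer[self.winner_outer - 1]["test_oacc"]


def _oacc_of(model: TrainedModel, data: LabeledDataset) -> float:
    return oacc(confusion(data.y, model.predict(data.X)))


def double_cv(data: LabeledDataset, spec: ModelSpec, seed: int = 0) -> CVReport:
    """Double 5-fold cross-validation; trains exactly 25 models.

    Ties on OACC break toward the lowest fold index (determinism).  The
    selected model is used as-is, without refitting on the full training
    set.
    """
    outer = stratified_kfold(data.y, K_FOLDS, _derive_seed(seed, 0))
    per_outer = []
    models_trained = 0
    for t in range(1, K_FOLDS + 1):
        train_idx = outer.train_indices(t)
        sub = data.subset(train_idx)
        inner = stratified_kfold(sub.y, K_FOLDS, _derive_seed(seed, t))
        best: Optional[tuple[float, int, TrainedModel]] = None
        for v in range(1, K_FOLDS + 1):
            calib = sub.subset(inner.train_indices(v))
            valid = sub.subset(inner.test_indices(v))
            try:
                model = train(spec.with_seed(_derive_seed(spec.seed, t, v)),
                              calib, outer_fold=t, inner_fold=v)
            except ValueError as err:
                raise ValueError(
                    f"training failed in outer fold {t}, inner fold {v}: {err}"
                ) from err
            models_trained += 1
            val_oacc = _oacc_of(model, valid)
            if best is None or val_oacc > best[0]:
                best = (val_oacc, v, model)
        val_oacc, v_sel, model_sel = best
        test_oacc = _oacc_of(model_sel, data.subset(outer.test_indices(t)))
        per_outer.append({"fold": t, "inner_selected": v_sel,
                          "val_oacc": val_oacc, "test_oacc": test_oacc,
                          "model": model_sel, "train_idx": train_idx,
                          "test_idx": outer.test_indices(t),
                          "inner_folds": inner})
    winner_outer = 1 + int(np.argmax([r["test_oacc"] for r in per_outer]))
    return CVReport(per_outer=per_outer, winner_outer=winner_outer,
                    winner_model=per_outer[winner_outer - 1]["model"],
                    models_trained=models_trained, outer_folds=outer)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

@dataclass
class ImageResult:
    """Per-image evaluation: held-out-fold and/or full-image metrics."""

    image_id: int
    test_fold_report: Optional[MetricReport] = None
    full_image_report: Optional[MetricReport] = None
    classification_map: Optional[ClassificationMap] = None


@dataclass
class ExperimentResult:
    images: list            # ImageResult per image
    models_trained: int
    detail: dict = field(default_factory=dict)


def _image_datasets(images, spec: ModelSpec) -> list[LabeledDataset]:
    return [build_dataset(cube, gt, spec, image_id=i)
            for i, (cube, gt) in enumerate(images)]


def _labeled_metrics(cmap: ClassificationMap, gt: GroundTruthMap) -> MetricReport:
    mask = gt.labels > 0
    return MetricReport.from_predictions(gt.labels[mask], cmap.labels[mask])


def run_experiment_a(
    images: list[tuple[HyperCube, GroundTruthMap]],
    spec: ModelSpec,
    seed: int = 0,
    predict_full_images: bool = True,
) -> ExperimentResult:
    """Intra-patient evaluation with triple 5-fold cross-validation.

    Each image's labeled pixels are stratified into five folds; for every
    fold-grouping g (the same g across all images) the other four folds of
    every image form the 80% training pool for a double CV, and the
    grouping with the best pooled held-out OACC wins.  Trains exactly
    5 x 25 models.
    """
    if len(images) < 2:
        raise ValueError("need at least two images")
    datasets = _image_datasets(images, spec)
    folds = [stratified_kfold(d.y, K_FOLDS, _derive_seed(seed, 100 + i))
             for i, d in enumerate(datasets)]
    groupings = []
    models_trained = 0
    for g in range(1, K_FOLDS + 1):
        train_pool = LabeledDataset.concat(
            [d.subset(f.train_indices(g)) for d, f in zip(datasets, folds)])
        cv = double_cv(train_pool, spec, seed=_derive_seed(seed, 200 + g))
        models_trained += cv.models_trained
        test_pool = LabeledDataset.concat(
            [d.subset(f.test_indices(g)) for d, f in zip(datasets, folds)])
        test_oacc = _oacc_of(cv.winner_model, test_pool)
        groupings.append({"grouping": g, "test_oacc": test_oacc, "cv": cv})
    g_best = 1 + int(np.argmax([r["test_oacc"] for r in groupings]))
    winner = groupings[g_best - 1]["cv"].winner_model

    results = []
    for i, (cube, gt) in enumerate(images):
        test = datasets[i].subset(folds[i].test_indices(g_best))
        fold_report = MetricReport.from_predictions(test.y, winner.predict(test.X))
        res = ImageResult(image_id=i, test_fold_report=fold_report)
        if predict_full_images:
            cmap = predict_image(winner, cube)
            res.classification_map = cmap
            res.full_image_report = _labeled_metrics(cmap, gt)
        results.append(res)
    return ExperimentResult(
        images=results, models_trained=models_trained,
        detail={"chosen_grouping": g_best, "winner_model": winner,
                "groupings": [{k: r[k] for k in ("grouping", "test_oacc")}
                              for r in groupings]})


def run_holdout(
    images: list[tuple[HyperCube, GroundTruthMap]],
    spec: ModelSpec,
    seed: int = 0,
    test_fold: int = 1,
) -> ExperimentResult:
    """Single Experiment-A-style 80/20 split: one training, pooled test.

    The outer structure of Experiment A (per-image stratified folds, the
    same fold grouping across images, 80% pooled training / 20% pooled
    test) with a single directly trained model instead of the full nested
    selection — the desk-scale variant used when one training is already
    expensive (the 3D-CNN).
    """
    datasets = _image_datasets(images, spec)
    folds = [stratified_kfold(d.y, K_FOLDS, _derive_seed(seed, 100 + i))
             for i, d in enumerate(datasets)]
    train_pool = LabeledDataset.concat(
        [d.subset(f.train_indices(test_fold)) for d, f in zip(datasets, folds)])
    model = train(spec.with_seed(_derive_seed(spec.seed, 300)), train_pool)
    results = []
    for i, (cube, gt) in enumerate(images):
        test = datasets[i].subset(folds[i].test_indices(test_fold))
        rep = MetricReport.from_predictions(test.y, model.predict(test.X))
        results.append(ImageResult(image_id=i, test_fold_report=rep))
    return ExperimentResult(images=results, models_trained=1,
                            detail={"winner_model": model,
                                    "test_fold": test_fold})


def run_experiment_b(
    images: list[tuple[HyperCube, GroundTruthMap]],
    spec: ModelSpec,
    seed: int = 0,
    predict_full_images: bool = True,
) -> ExperimentResult:
    """Inter-patient (leave-one-image-out) evaluation.

    For each held-out image, a double CV on the pooled labeled pixels of
    all other images selects the model, which then classifies the held-out
    image; metrics are reported on its labeled pixels.  Trains exactly
    n x 25 models; the selected model never sees its test image.
    """
    if len(images) < 2:
        raise ValueError("need at least two images")
    datasets = _image_datasets(images, spec)
    results = []
    models_trained = 0
    selected = []
    for i, (cube, gt) in enumerate(images):
        pool = LabeledDataset.concat([d for j, d in enumerate(datasets)
                                      if j != i])
        cv = double_cv(pool, spec, seed=_derive_seed(seed, 400 + i))
        models_trained += cv.models_trained
        selected.append(cv.winner_model)
        res = ImageResult(image_id=i)
        if predict_full_images:
            cmap = predict_image(cv.winner_model, cube)
            res.classification_map = cmap
            res.full_image_report = _labeled_metrics(cmap, gt)
        else:
            test = datasets[i]
            res.full_image_report = MetricReport.from_predictions(
                test.y, cv.winner_model.predict(test.X))
        results.append(res)
    return ExperimentResult(images=results, models_trained=models_trained,
                            detail={"selected_models": selected})
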