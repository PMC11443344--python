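"""End-to-end workflow: generate -> grade -> features -> select -> tune/train -> evaluate.

One seed drives every stochastic stage (image synthesis, the DBO search, model
initialization), so a rerun with the same configuration is byte-identical in
all written artifacts.  Grades are assigned by the segmentation chain itself
(not copied from the generator truth): the injury-ratio grading defines the
class labels exactly as it would on instrument imagery.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bilstm, evaluation, synthetic
from .dbo import DBOConfig
from .features import FeatureConfig, feature_table
from .grading import SegmentationConfig, grade_image
from .selection import select_features

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for a full synthetic-data run (defaults mirror the study design)."""

    seed: int = 0
    train_counts: tuple = synthetic.TABLE8_TRAIN_COUNTS
    test_counts: tuple = synthetic.TABLE8_TEST_COUNTS
    image_size: tuple = (96, 96)
    noise_sd: float = 8.0
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    tune: bool = True
    paper_mode: bool = False
    dbo_pop_size: int = 20
    dbo_iters: int = 8
    max_epochs: int = 500
    tune_epochs: int | None = None      # epochs per DBO fitness evaluation
    hidden_units: int = 200
    learning_rate: float = 0.001
    l2: float = 0.001


@dataclass
class PipelineResult:
    """Everything a run produces, before serialization."""

    config: PipelineConfig
    train_features: pd.DataFrame
    test_features: pd.DataFrame
    train_grades: list
    test_grades: list
    selected: list
    spearman_report: pd.DataFrame
    best_config: bilstm.BiLSTMConfig
    tuning_history: list
    cm: evaluation.ConfusionMatrix
    metrics: evaluation.MetricReport

    @property
    def accuracy(self) -> float:
        return self.metrics.accuracy


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _grade_split(images, seg) -> tuple[list, pd.DataFrame]:
    labels, rows = [], []
    for img in images:
        meas, g = grade_image(img, seg)
        labels.append(g.label)
        rows.append((img.id, meas.n_leaf, meas.n_injury, meas.lk, g.label))
    table = pd.DataFrame(rows, columns=["id", "n_leaf", "n_injury", "lk", "grade"])
    return labels, table


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage in order; optionally write all artifacts under ``outdir``."""
    ds = synthetic.make_dataset(config.seed, config.train_counts, config.test_counts,
                                size=config.image_size, noise_sd=config.noise_sd)

    train_grades, train_grade_table = _grade_split(ds.train, config.segmentation)
    test_grades, test_grade_table = _grade_split(ds.test, config.segmentation)

    # features are computed over the segmented leaf mask, like the grades
    from .grading import segment_leaf
    train_masks = [segment_leaf(im, config.segmentation) for im in ds.train]
    test_masks = [segment_leaf(im, config.segmentation) for im in ds.test]
    train_feat = feature_table(ds.train, train_masks, config.feature_config)
    test_feat = feature_table(ds.test, test_masks, config.feature_config)

    selected, spearman_report = select_features(train_feat, train_grades)
    if not selected:
        raise RuntimeError("stage feature_selection failed: empty selection")
    x_train = train_feat[selected].to_numpy()
    x_test = test_feat[selected].to_numpy()

    base = bilstm.BiLSTMConfig(hidden_units=config.hidden_units,
                               learning_rate=config.learning_rate,
                               l2=config.l2, max_epochs=config.max_epochs,
                               seed=config.seed)
    history: list = []
    if config.tune:
        tune_cfg = dataclasses.replace(
            base, max_epochs=config.tune_epochs or config.max_epochs)
        dbo_cfg = DBOConfig(bounds=bilstm.DEFAULT_SEARCH_BOUNDS,
                            pop_size=config.dbo_pop_size,
                            max_iter=config.dbo_iters, seed=config.seed)
        best, history = bilstm.tune_with_dbo(
            x_train, train_grades, x_test if config.paper_mode else None,
            test_grades if config.paper_mode else None,
            dbo_config=dbo_cfg, train_config=tune_cfg,
            paper_mode=config.paper_mode)
        best = dataclasses.replace(best, max_epochs=config.max_epochs)
    else:
        best = base

    model = bilstm.build(best, input_len=len(selected))
    model, _ = bilstm.train(model, x_train, train_grades, best)
    pred, _ = bilstm.predict(model, x_test)

    cm = evaluation.confusion(test_grades, pred)
    metrics = evaluation.report(cm)
    result = PipelineResult(config=config, train_features=train_feat,
                            test_features=test_feat, train_grades=train_grades,
                            test_grades=test_grades, selected=selected,
                            spearman_report=spearman_report, best_config=best,
                            tuning_history=list(history), cm=cm, metrics=metrics)
    if outdir is not None:
        _write_artifacts(result, train_grade_table, test_grade_table, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, train_grade_table, test_grade_table,
                     outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": result.config.seed, "config_hash": _config_hash(result.config),
            "config": dataclasses.asdict(result.config)}
    (outdir / "run.json").write_text(json.dumps(meta, indent=2, default=str))
    result.train_features.to_csv(outdir / "features_train.csv", float_format="%.10g")
    result.test_features.to_csv(outdir / "features_test.csv", float_format="%.10g")
    train_grade_table.to_csv(outdir / "grades_train.csv", index=False,
                             float_format="%.10g")
    test_grade_table.to_csv(outdir / "grades_test.csv", index=False,
                            float_format="%.10g")
    result.spearman_report.to_csv(outdir / "spearman.csv", index=False,
                                  float_format="%.10g")
    (outdir / "selection.json").write_text(json.dumps(result.selected, indent=2))
    (outdir / "metrics.json").write_text(
        evaluation.to_json(result.metrics, metadata=meta))
    (outdir / "confusion.csv").write_text(evaluation.confusion_csv(result.cm))
    (outdir / "f1_curve.csv").write_text(evaluation.f1_curve_csv(result.metrics))
    best = dataclasses.asdict(result.best_config)
    best["tuning_history"] = result.tuning_history
    (outdir / "best_config.json").write_text(json.dumps(best, indent=2))
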