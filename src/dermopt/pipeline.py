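"""End-to-end orchestration: segment → extract → select → tune → classify.

Training fits the Q-learning segmenter on (image, manual mask) pairs,
segments the training images with the frozen model, extracts the 19-value
feature vector from each segmented lesion, runs EFMO feature selection and
two-stage SVM tuning, and persists every stage artifact (JSON/CSV) plus a
manifest.  Testing applies the frozen artifacts to unseen images and emits
the five-metric row (Accuracy, Sensitivity, Specificity, PPV, NPV) and ROC
points.

One global seed drives every stochastic component, so identical configs
reproduce identical manifests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier, features, segmentation, selection


@dataclass
class PipelineConfig:
    seed: int = 0
    mode: int = 1
    segmenter: segmentation.SegmenterConfig | None = None
    feature_config: features.FeatureConfig | None = None
    selection_config: selection.SelectionConfig | None = None
    tune_config: classifier.TuneConfig | None = None

    def resolved(self):
        seg = self.segmenter or segmentation.SegmenterConfig(
            mode=self.mode, seed=self.seed)
        feat = self.feature_config or features.FeatureConfig()
        sel = self.selection_config or selection.SelectionConfig(seed=self.seed)
        tune = self.tune_config or classifier.TuneConfig(seed=self.seed)
        return seg, feat, sel, tune


@dataclass
class PipelineModel:
    """Frozen artifacts of one training run."""

    segmenter: segmentation.SegmenterModel
    feature_config: features.FeatureConfig
    selection_result: selection.SelectionResult
    gamma: float
    C: float
    svm: classifier.SVMModel
    train_metrics: classifier.ClassMetrics


def _segment_and_extract(images, model, feat_config):
    """Segment each image, extract features from the machine lesion mask.

    An image whose machine segmentation comes out empty falls back to the
    darkest-quartile threshold mask so a feature row always exists.
    """
    masks, rows = [], []
    for img in images:
        mask = segmentation.segment(img, model)
        if not mask.any():
            thr = np.quantile(img, 0.25)
            mask = (np.asarray(img) <= thr).astype(np.uint8)
        masks.append(mask)
        rows.append(features.extract_features(img, mask, feat_config))
    table = pd.DataFrame(rows, columns=list(features.FEATURE_NAMES))
    return masks, table


def _clean_table(table: pd.DataFrame) -> pd.DataFrame:
    """Replace undefined feature values (NaN sentinels) by column medians."""
    out = table.copy()
    for c in out.columns:
        if c == "label":
            continue
        col = out[c]
        if col.isna().any():
            med = col.median()
            out[c] = col.fillna(0.0 if np.isnan(med) else med)
    return out


def train_pipeline(images, masks, labels,
                   config: PipelineConfig | None = None) -> PipelineModel:
    """Train every stage on labeled (image, manual-mask) data."""
    config = config or PipelineConfig()
    labels = np.asarray(labels)
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    seg_cfg, feat_cfg, sel_cfg, tune_cfg = config.resolved()

    seg_model = segmentation.train_segmenter(list(zip(images, masks)), seg_cfg)
    _, table = _segment_and_extract(images, seg_model, feat_cfg)
    table = _clean_table(table)
    table["label"] = labels

    sel = selection.select_features(table, sel_cfg)
    gamma, C, svm = classifier.tune_gamma_then_C(table, sel.mask, tune_cfg)
    X = table.drop(columns="label").to_numpy()[:, sel.mask]
    train_metrics = classifier.evaluate(svm.predict(X), labels)
    return PipelineModel(seg_model, feat_cfg, sel, gamma, C, svm, train_metrics)


def predict_pipeline(model: PipelineModel, images):
    """Segment, extract and score unseen images; returns (labels, scores)."""
    if len(images) == 0:
        raise ValueError("empty test set")
    _, table = _segment_and_extract(images, model.segmenter, model.feature_config)
    table = _clean_table(table)
    X = table.to_numpy()[:, model.selection_result.mask]
    scores = model.svm.decision_function(X)
    return np.where(scores >= 0, 1, -1), scores


def evaluate_pipeline(model: PipelineModel, images, labels):
    """Apply the frozen model and compute metrics + ROC on labeled images."""
    preds, scores = predict_pipeline(model, images)
    m = classifier.evaluate(preds, np.asarray(labels))
    (fpr, tpr, thr), auc = classifier.roc_curve(scores, np.asarray(labels))
    m.auc = auc
    return m, (fpr, tpr, thr)


# -- file-based runs ---------------------------------------------------------

def save_model(model: PipelineModel, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "segmenter": outdir / "segmenter.json",
        "selection": outdir / "selected_features.json",
        "svm": outdir / "svm.json",
    }
    paths["segmenter"].write_text(model.segmenter.to_json())
    paths["selection"].write_text(model.selection_result.to_json())
    paths["svm"].write_text(model.svm.to_json())
    return {k: str(v) for k, v in paths.items()}


def load_model(outdir) -> PipelineModel:
    outdir = Path(outdir)
    seg = segmentation.SegmenterModel.from_json(
        (outdir / "segmenter.json").read_text())
    sel_data = json.loads((outdir / "selected_features.json").read_text())
    sel = selection.SelectionResult(np.asarray(sel_data["mask"], dtype=bool),
                                    sel_data["cost"], sel_data["features"])
    svm = classifier.SVMModel.from_json((outdir / "svm.json").read_text())
    return PipelineModel(seg, features.FeatureConfig(), sel, svm.gamma, svm.C,
                         svm, None)


def run_train(images, masks, labels, outdir,
              config: PipelineConfig | None = None) -> dict:
    """Train and persist all artifacts; returns the run manifest."""
    config = config or PipelineConfig()
    model = train_pipeline(images, masks, labels, config)
    paths = save_model(model, outdir)
    manifest = {
        "seed": config.seed,
        "mode": config.mode,
        "n_train": len(images),
        "artifacts": paths,
        "selected_features": model.selection_result.selected_names,
        "selection_cost": model.selection_result.cost,
        "gamma": model.gamma,
        "C": model.C,
        "train_metrics": model.train_metrics.as_row(),
    }
    manifest_path = Path(outdir) / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_test(images, labels, outdir) -> classifier.ClassMetrics:
    """Apply persisted artifacts to a test set; writes metrics + ROC CSVs."""
    model = load_model(outdir)
    m, (fpr, tpr, thr) = evaluate_pipeline(model, images, labels)
    outdir = Path(outdir)
    pd.DataFrame([m.as_row()]).to_csv(outdir / "test_metrics.csv", index=False)
    pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(
        outdir / "roc_points.csv", index=False)
    return m
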