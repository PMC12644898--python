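"""Gradient-boosted decision-tree models over motif count matrices.

Four modes: binary (one class vs background), multiclass (softmax over
all classes), multilabel (one binary ensemble per class) and
regression (continuous activity).  Defaults follow the study design:
up to 10,000 boosting rounds at learning rate 0.01, depth 6, 50%
row/column subsampling, early stopping after 100 stagnant validation
rounds, and a 0.5 decision threshold.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xgboost as xgb

from .bag_matrix import MotifCountMatrix

_EVAL_METRICS = {"binary": "logloss", "multiclass": "mlogloss",
                 "multilabel": "logloss", "regression": "rmse"}
_OBJECTIVES = {"binary": "binary:logistic", "multiclass": "multi:softprob",
               "multilabel": "binary:logistic", "regression": "reg:squarederror"}


@dataclass
class TrainConfig:
    mode: str = "binary"
    rounds: int = 10_000
    learning_rate: float = 0.01
    max_depth: int = 6
    row_subsample: float = 0.5
    column_subsample: float = 0.5
    early_stopping_rounds: int = 100
    eval_metric: str | None = None
    nthread: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in _OBJECTIVES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        if not (0 < self.row_subsample <= 1 and 0 < self.column_subsample <= 1):
            raise ValueError("subsample fractions must be in (0, 1]")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.eval_metric is None:
            self.eval_metric = _EVAL_METRICS[self.mode]

    def xgb_params(self, num_class: int | None = None) -> dict:
        params = {
            "objective": _OBJECTIVES[self.mode],
            "eta": self.learning_rate,
            "max_depth": self.max_depth,
            "subsample": self.row_subsample,
            "colsample_bytree": self.column_subsample,
            "eval_metric": self.eval_metric,
            "nthread": self.nthread,
            "seed": self.seed,
        }
        if self.mode == "multiclass":
            params["num_class"] = num_class
        return params


@dataclass
class ModelBundle:
    """Trained ensemble(s) plus everything needed to reapply them."""

    boosters: dict[str, xgb.Booster]   # key: "model" or class name (multilabel)
    feature_names: list[str]
    class_names: list[str]
    config: TrainConfig
    best_iterations: dict[str, int] = field(default_factory=dict)
    history: dict[str, dict] = field(default_factory=dict)

    @property
    def mode(self) -> str:
        return self.config.mode


def _dmatrix(counts: pd.DataFrame, feature_names: list[str],
             label=None) -> xgb.DMatrix:
    X = counts[feature_names].to_numpy(dtype=np.float32)
    return xgb.DMatrix(X, label=label, feature_names=feature_names)


def _align_columns(matrix: MotifCountMatrix, feature_names: list[str],
                   strict: bool = True) -> pd.DataFrame:
    """Reorder columns to the training vocabulary; absent motifs count 0."""
    extra = [c for c in matrix.col_ids if c not in set(feature_names)]
    if extra and strict:
        raise ValueError(f"unknown feature columns: {extra}")
    df = matrix.counts.reindex(columns=feature_names, fill_value=0)
    return df


def _encode_labels(labels: pd.Series, class_names: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_names)}
    return np.array([index[str(l)] for l in labels], dtype=np.int64)


def train(train_matrix: MotifCountMatrix, train_labels,
          valid_matrix: MotifCountMatrix, valid_labels,
          config: TrainConfig | None = None) -> ModelBundle:
    """Fit a boosted-tree ensemble with validation-based early stopping.

    `train_labels` / `valid_labels`: a pandas Series of class names
    (binary/multiclass), a 0/1 DataFrame with one column per class
    (multilabel), or a numeric Series (regression).
    """
    config = config or TrainConfig()
    if list(train_matrix.col_ids) != list(valid_matrix.col_ids):
        raise ValueError("train and validation matrices must share columns")
    feature_names = list(train_matrix.col_ids)
    boosters: dict[str, xgb.Booster] = {}
    best: dict[str, int] = {}
    history: dict[str, dict] = {}

    def _fit(key: str, y_train, y_valid, params):
        dtrain = _dmatrix(train_matrix.counts, feature_names, y_train)
        dvalid = _dmatrix(valid_matrix.counts, feature_names, y_valid)
        evals_result: dict = {}
        booster = xgb.train(
            params, dtrain, num_boost_round=config.rounds,
            evals=[(dvalid, "validation")],
            early_stopping_rounds=config.early_stopping_rounds,
            evals_result=evals_result, verbose_eval=False)
        boosters[key] = booster
        best[key] = int(getattr(booster, "best_iteration", config.rounds - 1))
        history[key] = evals_result

    if config.mode == "binary":
        y_tr = np.asarray(train_labels, dtype=float)
        y_va = np.asarray(valid_labels, dtype=float)
        if len(np.unique(y_tr)) < 2:
            raise ValueError("binary training labels contain a single class")
        class_names = ["negative", "positive"]
        _fit("model", y_tr, y_va, config.xgb_params())
    elif config.mode == "multiclass":
        tr = pd.Series(train_labels)
        va = pd.Series(valid_labels)
        class_names = sorted(set(map(str, tr)) | set(map(str, va)))
        _fit("model", _encode_labels(tr, class_names),
             _encode_labels(va, class_names),
             config.xgb_params(num_class=len(class_names)))
    elif config.mode == "multilabel":
        y_tr = pd.DataFrame(train_labels)
        y_va = pd.DataFrame(valid_labels)
        class_names = list(y_tr.columns)
        for cls in class_names:
            _fit(cls, y_tr[cls].to_numpy(dtype=float),
                 y_va[cls].to_numpy(dtype=float), config.xgb_params())
    else:  # regression
        class_names = []
        _fit("model", np.asarray(train_labels, dtype=float),
             np.asarray(valid_labels, dtype=float), config.xgb_params())

    return ModelBundle(boosters, feature_names, class_names, config, best, history)


def predict(bundle: ModelBundle, matrix: MotifCountMatrix,
            threshold: float = 0.5, strict: bool = True,
            output_margin: bool = False) -> pd.DataFrame:
    """Score rows; labels use the >= threshold rule (binary/multilabel).

    Returns a DataFrame indexed by row id: binary -> score/label;
    multiclass -> one probability column per class + label; multilabel
    -> per-class probability and label columns; regression -> value.
    """
    counts = _align_columns(matrix, bundle.feature_names, strict=strict)
    dmat = _dmatrix(counts, bundle.feature_names)
    mode = bundle.mode
    index = counts.index

    def _pred(key):
        booster = bundle.boosters[key]
        it = (0, best + 1) if (best := bundle.best_iterations.get(key)) is not None else None
        return booster.predict(dmat, iteration_range=it, output_margin=output_margin)

    if mode == "binary":
        score = _pred("model")
        return pd.DataFrame({"score": score,
                             "label": (score >= threshold).astype(int)}, index=index)
    if mode == "multiclass":
        probs = _pred("model")
        df = pd.DataFrame(probs, index=index, columns=bundle.class_names)
        df["label"] = df[bundle.class_names].idxmax(axis=1)
        return df
    if mode == "multilabel":
        df = pd.DataFrame(index=index)
        for cls in bundle.class_names:
            p = _pred(cls)
            df[f"score_{cls}"] = p
            df[f"label_{cls}"] = (p >= threshold).astype(int)
        return df
    return pd.DataFrame({"value": _pred("model")}, index=index)


def save_bundle(bundle: ModelBundle, directory: str) -> None:
    """Persist as native JSON booster dumps plus a manifest."""
    os.makedirs(directory, exist_ok=True)
    for key, booster in bundle.boosters.items():
        booster.save_model(os.path.join(directory, f"{key}.json"))
    manifest = {
        "feature_names": bundle.feature_names,
        "class_names": bundle.class_names,
        "config": asdict(bundle.config),
        "best_iterations": bundle.best_iterations,
        "boosters": list(bundle.boosters),
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_bundle(directory: str) -> ModelBundle:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    config = TrainConfig(**manifest["config"])
    boosters = {}
    for key in manifest["boosters"]:
        booster = xgb.Booster()
        booster.load_model(os.path.join(directory, f"{key}.json"))
        boosters[key] = booster
    return ModelBundle(boosters, manifest["feature_names"], manifest["class_names"],
                       config, {k: int(v) for k, v in manifest["best_iterations"].items()})
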