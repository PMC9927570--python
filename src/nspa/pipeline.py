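"""Leakage-aware evaluation of the delta-degree transform.

The transform is a fitted feature map: the per-edge class tables must be
estimated on training subjects only, then applied to both training and held
out subjects. Every routine here enforces that discipline:

* :func:`cv_transform_evaluate` - stratified k-fold CV; tables are refitted
  on each fold's training subjects before transforming both folds;
* :func:`baseline_evaluate` - identical folds on the raw {0,1,2} codes;
* :func:`holdout_protocol` - an 80/20 stratified split where the pair
  scores, network and component selection come from the 80% alone, with CV
  run inside it and one final evaluation on the untouched 20%;
* :func:`resampling_importance` - repeated 80% subsampling without
  replacement; each replicate refits the tables and a logistic regression,
  and coefficients are averaged across replicates.

Models: L2-penalised logistic regression (LBFGS, C=1.0, no feature scaling -
delta degrees are small integers) or a 500-tree random forest baseline.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data import Dataset
from .infotheory import all_pairs_information_gain
from .network import EpistasisNetwork, select_components
from .portrait import delta_degree_transform, fit_pair_statistics

__all__ = [
    "ModelSpec",
    "MetricsTable",
    "ImportanceReport",
    "HoldoutResult",
    "cv_transform_evaluate",
    "baseline_evaluate",
    "per_component_evaluate",
    "holdout_protocol",
    "resampling_importance",
]


@dataclasses.dataclass
class ModelSpec:
    """Classifier configuration.

    kind is "logistic_regression" (C = inverse L2 strength) or
    "random_forest" (n_estimators trees).
    """

    kind: str = "logistic_regression"
    C: float = 1.0
    n_estimators: int = 500
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.kind not in ("logistic_regression", "random_forest"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.C <= 0 or self.n_estimators <= 0:
            raise ValueError("model parameters must be positive")

    def build(self, seed: int):
        if self.kind == "logistic_regression":
            # sklearn's default penalty is L2; C is its inverse strength
            return LogisticRegression(C=self.C, solver="lbfgs", max_iter=self.max_iter)
        return RandomForestClassifier(n_estimators=self.n_estimators, random_state=seed)


@dataclasses.dataclass
class MetricsTable:
    """Per-class precision/recall/F1 plus overall accuracy.

    ``per_fold`` holds one row per fold; the headline attributes are
    fold-averaged for the per-class metrics and pooled (correct/total over
    all held-out predictions) for accuracy.
    """

    per_fold: pd.DataFrame
    y_true: np.ndarray
    y_pred: np.ndarray

    @staticmethod
    def _fold_row(y_true, y_pred) -> dict:
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=[1, 0], zero_division=0
        )
        return {
            "precision_case": p[0],
            "precision_control": p[1],
            "recall_case": r[0],
            "recall_control": r[1],
            "f1_case": f[0],
            "f1_control": f[1],
            "accuracy": float(np.mean(np.asarray(y_true) == np.asarray(y_pred))),
        }

    @classmethod
    def from_folds(cls, fold_results: list[tuple[np.ndarray, np.ndarray]]) -> "MetricsTable":
        rows = [cls._fold_row(t, p) for t, p in fold_results]
        y_true = np.concatenate([t for t, _ in fold_results])
        y_pred = np.concatenate([p for _, p in fold_results])
        return cls(pd.DataFrame(rows), y_true, y_pred)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))

    def mean(self, metric: str) -> float:
        return float(self.per_fold[metric].mean())

    def summary(self) -> pd.DataFrame:
        agg = self.per_fold.mean().to_frame().T
        agg["accuracy"] = self.accuracy
        agg.index = ["mean"]
        return agg


def _check_folds(y: np.ndarray, k: int) -> None:
    n_case = int(y.sum())
    n_ctl = len(y) - n_case
    if n_case < k or n_ctl < k:
        raise ValueError(
            f"need at least {k} subjects per class for {k}-fold stratified CV "
            f"(have {n_case} cases, {n_ctl} controls)"
        )


def _fit_predict(model: ModelSpec, seed: int, X_tr, y_tr, X_te) -> np.ndarray:
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training fold contains a single class; use stratification or more data")
    est = model.build(seed)
    est.fit(X_tr, y_tr)
    return est.predict(X_te)


def cv_transform_evaluate(
    dataset: Dataset,
    network: EpistasisNetwork,
    model: ModelSpec | None = None,
    k: int = 5,
    seed: int = 0,
) -> MetricsTable:
    """Stratified k-fold CV of a classifier on delta-degree features.

    For each fold the pair tables are fitted on the k-1 training folds only,
    the transform is applied to both folds, and the model is fitted on the
    transformed training fold.
    """
    model = model or ModelSpec()
    y = dataset.phenotype.labels
    _check_folds(y, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
        train = dataset.subset_subjects(tr_idx)
        test = dataset.subset_subjects(te_idx)
        stats = fit_pair_statistics(train, network)
        X_tr = delta_degree_transform(train, network, stats).values
        X_te = delta_degree_transform(test, network, stats).values
        y_pred = _fit_predict(model, seed, X_tr, y[tr_idx], X_te)
        folds.append((y[te_idx], y_pred))
    return MetricsTable.from_folds(folds)


def baseline_evaluate(
    dataset: Dataset,
    variant_subset: list[str] | None = None,
    model: ModelSpec | None = None,
    k: int = 5,
    seed: int = 0,
) -> MetricsTable:
    """Identical CV folds fitted on the raw allele-count codes (no transform)."""
    model = model or ModelSpec()
    if variant_subset is not None:
        dataset = dataset.subset_variants(variant_subset)
    y = dataset.phenotype.labels
    _check_folds(y, k)
    X = dataset.genotypes.codes.astype(float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
        y_pred = _fit_predict(model, seed, X[tr_idx], y[tr_idx], X[te_idx])
        folds.append((y[te_idx], y_pred))
    return MetricsTable.from_folds(folds)


def per_component_evaluate(
    dataset: Dataset,
    network: EpistasisNetwork,
    components: list[set[str]],
    model: ModelSpec | None = None,
    k: int = 5,
    seed: int = 0,
) -> dict[int, MetricsTable]:
    """CV of the transform restricted to each component's induced subnetwork."""
    out: dict[int, MetricsTable] = {}
    for idx, comp in enumerate(components):
        if not comp:
            warnings.warn(f"component {idx} is empty; skipped", stacklevel=2)
            continue
        sub = network.induced(comp)
        out[idx] = cv_transform_evaluate(dataset, sub, model, k=k, seed=seed)
    return out


@dataclasses.dataclass
class HoldoutResult:
    """Everything the 80/20 protocol produced, for overfitting inspection."""

    network: EpistasisNetwork
    components: list[set[str]]
    train_metrics: MetricsTable
    test_metrics: MetricsTable
    validation_metrics: MetricsTable
    train_subject_ids: list[str]
    validation_subject_ids: list[str]


def holdout_protocol(
    dataset: Dataset,
    tau: float,
    min_component_size: int = 0,
    holdout_fraction: float = 0.2,
    model: ModelSpec | None = None,
    k: int = 5,
    seed: int = 0,
) -> HoldoutResult:
    """80/20 stratified holdout with the network built from the 80% only.

    Pair scores, threshold and component selection use training subjects
    exclusively; CV runs inside the training split (test surface); the final
    model, fitted on the whole transformed training split, is evaluated once
    on the untouched validation split.
    """
    model = model or ModelSpec()
    y = dataset.phenotype.labels
    idx = np.arange(len(y))
    tr_idx, va_idx = train_test_split(
        idx, test_size=holdout_fraction, stratify=y, random_state=seed
    )
    train = dataset.subset_subjects(np.sort(tr_idx))
    validation = dataset.subset_subjects(np.sort(va_idx))
    train.phenotype.require_both_classes()
    validation.phenotype.require_both_classes()

    scores = all_pairs_information_gain(train)
    from .network import build_network  # local import avoids cycle at module load

    net = build_network(scores, tau)
    selected = select_components(net, min_component_size)
    if selected:
        keep = set().union(*(comp for comp, _ in selected))
        net = net.induced(keep)
        components = [comp for comp, _ in selected]
    else:
        warnings.warn("no component exceeded min_component_size; using the full network", stacklevel=2)
        components = []
    if net.n_edges == 0:
        raise ValueError("training-split network is empty at this threshold")

    test_metrics = cv_transform_evaluate(train, net, model, k=k, seed=seed)

    stats = fit_pair_statistics(train, net)
    X_tr = delta_degree_transform(train, net, stats).values
    X_va = delta_degree_transform(validation, net, stats).values
    est = model.build(seed)
    est.fit(X_tr, train.phenotype.labels)
    train_metrics = MetricsTable.from_folds([(train.phenotype.labels, est.predict(X_tr))])
    validation_metrics = MetricsTable.from_folds(
        [(validation.phenotype.labels, est.predict(X_va))]
    )
    return HoldoutResult(
        net,
        components,
        train_metrics,
        test_metrics,
        validation_metrics,
        list(train.subject_ids),
        list(validation.subject_ids),
    )


@dataclasses.dataclass
class ImportanceReport:
    """Averaged logistic-regression coefficients across subsample replicates."""

    table: pd.DataFrame  # index: variant; columns: mean_coefficient, mean_abs_coefficient
    n_replicates: int

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.sort_values("mean_abs_coefficient", ascending=False).head(n)


def resampling_importance(
    dataset: Dataset,
    network: EpistasisNetwork,
    replicates: int = 100,
    fraction: float = 0.8,
    model: ModelSpec | None = None,
    seed: int = 0,
) -> ImportanceReport:
    """Feature importance by repeated stratified subsampling without replacement.

    Each replicate draws floor(fraction * n_class) subjects from each class,
    refits the pair tables and the transform on the draw, fits a logistic
    regression, and records its coefficient vector. The report gives the
    signed mean and the mean absolute coefficient per connected variant.
    """
    model = model or ModelSpec()
    if model.kind != "logistic_regression":
        raise ValueError("resampling importance is defined for logistic regression coefficients")
    y = dataset.phenotype.labels
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(y == 1)
    ctl_idx = np.flatnonzero(y == 0)
    n_case = int(np.floor(fraction * len(case_idx)))
    n_ctl = int(np.floor(fraction * len(ctl_idx)))
    if n_case < 1 or n_ctl < 1:
        raise ValueError("subsample would miss a class; increase fraction or data size")
    coefs = np.zeros((replicates, len(network.nodes)))
    for r in range(replicates):
        draw = np.sort(
            np.concatenate(
                [
                    rng.choice(case_idx, size=n_case, replace=False),
                    rng.choice(ctl_idx, size=n_ctl, replace=False),
                ]
            )
        )
        sub = dataset.subset_subjects(draw)
        stats = fit_pair_statistics(sub, network)
        X = delta_degree_transform(sub, network, stats).values
        est = model.build(seed)
        est.fit(X, y[draw])
        coefs[r] = est.coef_[0]
    table = pd.DataFrame(
        {
            "mean_coefficient": coefs.mean(axis=0),
            "mean_abs_coefficient": np.abs(coefs).mean(axis=0),
            "se_coefficient": coefs.std(axis=0, ddof=1) / np.sqrt(replicates)
            if replicates > 1
            else np.zeros(coefs.shape[1]),
        },
        index=network.nodes,
    )
    return ImportanceReport(table, replicates)
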