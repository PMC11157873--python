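"""Classifier evaluation harness: five models, stratified splits,
5-fold cross-validation with 95% CIs, and paired comparison of the
with/without-harmonization arms including feature-importance rank shifts.

Model roster and hyperparameters (the study's settings):

==============  ==========================================================
lasso           L1 linear regression (alpha 0.1, 1000 iterations) used as
                a classifier by thresholding the continuous prediction
                at 0.5; the prediction doubles as the ranking score
logistic        logistic regression, L2 penalty
random_forest   100 trees, maximum depth 8
svm             RBF kernel, C=2, gamma='scale'
neural_net      MLP, ReLU, SGD, learning rate 0.01, 200 iterations,
                5 hidden layers (32 units each — width is configurable)
==============  ==========================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .datatypes import FeatureTable

__all__ = [
    "ModelSpec", "SplitPlan", "MODEL_NAMES", "default_model_specs",
    "make_split", "train_eval", "cross_validate", "compare_arms",
    "EvalReport",
]

MODEL_NAMES = ("lasso", "logistic", "random_forest", "svm", "neural_net")

_DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "lasso": {"alpha": 0.1, "max_iter": 1000},
    "logistic": {"penalty": "l2"},
    "random_forest": {"n_estimators": 100, "max_depth": 8},
    "svm": {"C": 2.0, "kernel": "rbf", "gamma": "scale"},
    "neural_net": {
        "activation": "relu", "solver": "sgd", "learning_rate_init": 0.01,
        "max_iter": 200, "hidden_layer_sizes": (32, 32, 32, 32, 32),
    },
}


@dataclass
class ModelSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")
        required = set(_DEFAULT_HYPERPARAMS[self.name])
        missing = required - set(self.hyperparameters)
        if self.hyperparameters and missing:
            raise ValueError(
                f"{self.name}: missing hyperparameters {sorted(missing)}"
            )
        if not self.hyperparameters:
            self.hyperparameters = dict(_DEFAULT_HYPERPARAMS[self.name])

    def build(self):
        h = self.hyperparameters
        if self.name == "lasso":
            return Lasso(alpha=h["alpha"], max_iter=h["max_iter"])
        if self.name == "logistic":
            if h["penalty"] != "l2":
                raise ValueError("only the study's l2 penalty is supported")
            # l2 is sklearn's default; passing it explicitly is deprecated
            return LogisticRegression(max_iter=1000, random_state=self.seed)
        if self.name == "random_forest":
            return RandomForestClassifier(
                n_estimators=h["n_estimators"], max_depth=h["max_depth"],
                random_state=self.seed,
            )
        if self.name == "svm":
            return SVC(C=h["C"], kernel=h["kernel"], gamma=h["gamma"],
                       random_state=self.seed)
        return MLPClassifier(
            activation=h["activation"], solver=h["solver"],
            learning_rate_init=h["learning_rate_init"],
            max_iter=h["max_iter"],
            hidden_layer_sizes=tuple(h["hidden_layer_sizes"]),
            random_state=self.seed,
        )


def default_model_specs(seed: int = 0) -> list[ModelSpec]:
    return [ModelSpec(name, seed=seed) for name in MODEL_NAMES]


# ---------------------------------------------------------------------------
# splitting


@dataclass
class SplitPlan:
    train_indices: np.ndarray
    test_indices: np.ndarray
    ratio: float
    stratified: bool
    seed: int


def make_split(table: FeatureTable, ratio: float = 0.8,
               seed: int = 0) -> SplitPlan:
    """Deterministic stratified train/test split by class label."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    counts = np.bincount(table.class_labels, minlength=2)
    if counts.min() < 5:
        raise ValueError("need at least 5 samples per class to split")
    idx = np.arange(table.n_samples)
    train, test = train_test_split(
        idx, train_size=ratio, stratify=table.class_labels,
        random_state=seed,
    )
    for part, label in ((train, "train"), (test, "test")):
        if len(np.unique(table.class_labels[part])) < 2:
            raise ValueError(f"class missing from the {label} split")
    return SplitPlan(np.sort(train), np.sort(test), ratio, True, seed)


# ---------------------------------------------------------------------------
# metrics


def _confusion_metrics(y_true, y_pred) -> dict[str, float]:
    tp = float(np.sum((y_true == 1) & (y_pred == 1)))
    tn = float(np.sum((y_true == 0) & (y_pred == 0)))
    fp = float(np.sum((y_true == 0) & (y_pred == 1)))
    fn = float(np.sum((y_true == 1) & (y_pred == 0)))
    acc = (tp + tn) / max(tp + tn + fp + fn, 1.0)
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    rec = tp / (tp + fn) if tp + fn > 0 else 0.0
    return {"accuracy": acc, "precision": prec, "recall": rec}


def _auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def _scores(model, name: str, X: np.ndarray) -> np.ndarray:
    if name == "lasso":
        return model.predict(X)
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def train_eval(spec: ModelSpec, X_train, y_train, X_test, y_test):
    """Fit one model and score it on held-out data.

    Features are standardized with training statistics only; the fitted
    handle, scaler moments, metrics and ROC curve are all returned.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data contains a single class")
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xtr = (X_train - mu) / sd
    Xte = (X_test - mu) / sd

    model = spec.build()
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*didn't converge.*")
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        model.fit(Xtr, y_train)
    score = _scores(model, spec.name, Xte)
    if spec.name == "lasso":
        y_pred = (score >= 0.5).astype(int)
    else:
        y_pred = model.predict(Xte)

    metrics = _confusion_metrics(np.asarray(y_test), y_pred)
    fpr, tpr, _ = _sk_roc_curve(y_test, score)
    metrics["auc"] = _auc_trapezoid(fpr, tpr)
    return {
        "metrics": metrics,
        "roc_curve": (fpr, tpr),
        "model": model,
        "scaler": (mu, sd),
    }


def feature_importances(model, name: str) -> np.ndarray | None:
    """|coefficients| for linear models, impurity importances for forests."""
    if name in ("lasso",):
        return np.abs(model.coef_)
    if name == "logistic":
        return np.abs(model.coef_[0])
    if name == "random_forest":
        return model.feature_importances_.copy()
    return None


def ci95(values: np.ndarray) -> tuple[float, list[float]]:
    """Normal-approximation 95% CI over fold metrics:
    mean +/- 1.96 sd / sqrt(k), clipped to [0, 1]."""
    values = np.asarray(values, dtype=float)
    k = values.size
    mean = float(values.mean())
    half = 1.96 * float(values.std(ddof=1)) / np.sqrt(k) if k > 1 else 0.0
    return mean, [max(0.0, mean - half), min(1.0, mean + half)]


def cross_validate(spec: ModelSpec, table: FeatureTable, k: int = 5,
                   seed: int = 0) -> dict:
    """Stratified k-fold CV; per-metric mean and normal-approximation
    95% CI (mean +/- 1.96 sd / sqrt(k), clipped to [0, 1])."""
    y = table.class_labels
    if k > table.n_samples:
        raise ValueError("k exceeds the number of samples")
    if k > np.bincount(y).min():
        raise ValueError("k exceeds the minority class count")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics: list[dict[str, float]] = []
    for tr, te in skf.split(table.values, y):
        res = train_eval(spec, table.values[tr], y[tr],
                         table.values[te], y[te])
        fold_metrics.append(res["metrics"])
    out = {"model": spec.name, "k": k, "folds": fold_metrics, "summary": {}}
    for metric in ("accuracy", "precision", "recall", "auc"):
        vals = np.array([fm[metric] for fm in fold_metrics])
        mean, ci = ci95(vals)
        out["summary"][metric] = {"mean": mean, "ci95": ci}
    return out


# ---------------------------------------------------------------------------
# arm comparison


@dataclass
class EvalReport:
    """Per-arm evaluation: CV summaries, test-set ROC and importances."""

    arm: str
    cv: dict[str, dict]                     # model -> cross_validate output
    roc: dict[str, tuple]                   # model -> (fpr, tpr)
    importances: dict[str, dict[str, float]]  # model -> feature -> score
    feature_names: list[str] = field(default_factory=list)


def evaluate_arm(
    table: FeatureTable,
    arm: str,
    specs: list[ModelSpec] | None = None,
    k: int = 5,
    seed: int = 0,
    ratio: float = 0.8,
) -> EvalReport:
    """CV metrics plus one held-out-split ROC/importances per model."""
    specs = specs or default_model_specs(seed)
    split = make_split(table, ratio=ratio, seed=seed)
    cv, roc, imps = {}, {}, {}
    for spec in specs:
        cv[spec.name] = cross_validate(spec, table, k=k, seed=seed)
        res = train_eval(
            spec,
            table.values[split.train_indices],
            table.class_labels[split.train_indices],
            table.values[split.test_indices],
            table.class_labels[split.test_indices],
        )
        roc[spec.name] = res["roc_curve"]
        scores = feature_importances(res["model"], spec.name)
        if scores is not None:
            imps[spec.name] = dict(
                zip(table.feature_names, map(float, scores))
            )
    return EvalReport(arm, cv, roc, imps, list(table.feature_names))


def _rank(scores: dict[str, float]) -> dict[str, int]:
    ordered = sorted(scores, key=lambda n: (-scores[n], n))
    return {n: r + 1 for r, n in enumerate(ordered)}


def compare_arms(report_without: EvalReport,
                 report_with: EvalReport) -> dict:
    """Paired metric deltas (with - without) per model, plus importance
    rank shifts and the Spearman correlation of the two rankings."""
    if set(report_without.cv) != set(report_with.cv):
        raise ValueError("arms evaluated different model lists")
    out: dict = {"deltas": {}, "importance": {}}
    for model in report_without.cv:
        out["deltas"][model] = {
            metric: report_with.cv[model]["summary"][metric]["mean"]
            - report_without.cv[model]["summary"][metric]["mean"]
            for metric in ("accuracy", "precision", "recall", "auc")
        }
    for model in report_without.importances:
        if model not in report_with.importances:
            continue
        r0 = _rank(report_without.importances[model])
        r1 = _rank(report_with.importances[model])
        common = sorted(set(r0) & set(r1))
        rho = float(_stats.spearmanr(
            [r0[n] for n in common], [r1[n] for n in common]
        ).statistic)
        out["importance"][model] = {
            "spearman_rho": rho,
            "rank_change": {n: r0[n] - r1[n] for n in common},
        }
    return out
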