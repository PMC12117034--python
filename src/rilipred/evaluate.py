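"""Model evaluation: stratified splits, cross-validation, ROC/AUC, pipeline.

Accuracy is reported three ways, mirroring how small-cohort studies in this
area present results:

* resubstitution — the fitted model scored on its own training rows (this
  is the only sense in which a squared-inverse-weighted kNN can reach
  exactly 100%);
* cross-validation — unweighted mean of per-fold holdout accuracies over a
  stratified k-fold plan (k = 5 by default);
* holdout — accuracy on a stratified train/test partition (159:83 by
  default, matching the published cohort split of 242 patients).

ROC curves sweep the unique score values; AUC is the trapezoidal integral
and equals the concordance (pair-counting, ties counted 1/2) statistic.
:func:`run_pipeline` chains simulate/load -> HPF scoring -> group
comparisons -> model training -> evaluation into one deterministic report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import stats as cohort_stats
from .errors import ConfigurationError
from .features import FEATURE_COLUMNS
from .hpf import HPFThresholdClassifier, hpf_scores
from .models import (
    DistanceWeightedKNNClassifier,
    GiniTreeClassifier,
    RandomFeatureKernelLogistic,
)
from .synthetic import CohortConfig, sample_feature_table

__all__ = [
    "SplitPlan",
    "EvalResult",
    "PipelineConfig",
    "stratified_kfold",
    "holdout_split",
    "accuracy",
    "roc_curve",
    "auc",
    "make_model",
    "design_matrix",
    "model_scores",
    "cross_validate",
    "evaluate_holdout",
    "run_pipeline",
    "report_to_json",
    "report_to_csvs",
    "MODEL_NAMES",
]

MODEL_NAMES = ("tree", "knn", "kernel", "hpf")


@dataclass(frozen=True)
class SplitPlan:
    """A stratified k-fold assignment: fold_of[i] in {0..k-1}."""

    fold_of: np.ndarray
    k: int
    seed: int
    stratified: bool = True

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.fold_of == fold)
        train = np.flatnonzero(self.fold_of != fold)
        return train, test


@dataclass
class EvalResult:
    """Accuracies (percent), per-fold detail and a pooled ROC."""

    resubstitution_accuracy: float = float("nan")
    cv_fold_accuracies: list[float] = field(default_factory=list)
    cv_accuracy: float = float("nan")
    holdout_accuracy: float | None = None
    roc_points: np.ndarray | None = None
    auc: float = float("nan")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if self.roc_points is not None:
            d["roc_points"] = np.round(self.roc_points, 6).tolist()
        return d


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> SplitPlan:
    """Deterministic stratified k-fold; per-fold class counts within 1.

    Each class's shuffled members are split into chunks of size
    floor(n_c/k) or that plus one; the larger chunks go to the folds that
    are currently smallest (ties to the lower fold index), which keeps fold
    sizes as even as possible.
    """
    labels = np.asarray(labels)
    n = labels.size
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    fold_sizes = np.zeros(k, dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < k:
            raise ConfigurationError(
                f"class {c!r} has {idx.size} members, fewer than k={k}"
            )
        rng.shuffle(idx)
        counts = np.full(k, idx.size // k)
        rem = idx.size - counts.sum()
        order = np.lexsort((np.arange(k), fold_sizes))
        counts[order[:rem]] += 1
        start = 0
        for f in range(k):
            fold_of[idx[start : start + counts[f]]] = f
            start += counts[f]
        fold_sizes += counts
    return SplitPlan(fold_of=fold_of, k=k, seed=seed)


def holdout_split(
    table: pd.DataFrame, n_train: int = 159, seed: int = 0, stratified: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a labelled table into (train, test) of sizes (n_train, n - n_train).

    Stratification allocates floor(n_c * n_train / n) per class and hands
    the remaining slots to the classes with the largest fractional parts,
    so class proportions are preserved within one sample.
    """
    n = len(table)
    if not 0 < n_train < n:
        raise ConfigurationError(f"need 0 < n_train < {n}, got {n_train}")
    rng = np.random.default_rng(seed)
    if stratified:
        if "rili" not in table.columns:
            raise ConfigurationError("stratified split needs a 'rili' column")
        labels = table["rili"].to_numpy()
        classes = np.unique(labels)
        exact = {c: (labels == c).sum() * n_train / n for c in classes}
        take = {c: int(np.floor(exact[c])) for c in classes}
        short = n_train - sum(take.values())
        for c in sorted(classes, key=lambda c: (-(exact[c] - take[c]), c))[:short]:
            take[c] += 1
        train_idx = []
        for c in classes:
            idx = np.flatnonzero(labels == c)
            rng.shuffle(idx)
            train_idx.extend(idx[: take[c]])
        train_idx = np.sort(np.asarray(train_idx))
    else:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return table.iloc[mask].reset_index(drop=True), table.iloc[~mask].reset_index(drop=True)


def accuracy(pred, truth) -> float:
    """Percent agreement, 100 * matches / n."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.size != truth.size or pred.size == 0:
        raise ValueError(f"length mismatch or empty: {pred.size} vs {truth.size}")
    return 100.0 * float((pred == truth).mean())


def roc_curve(scores, labels, positive_low: bool = False) -> np.ndarray:
    """(FPR, TPR) points from a threshold sweep over unique score values.

    With ``positive_low=True`` low scores favour the positive class (the
    HPF orientation). Returns an (m, 2) array from (0, 0) to (1, 1),
    monotone non-decreasing in both coordinates.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.size != labels.size or scores.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int((labels == 1).sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    s = -scores if positive_low else scores
    order = np.argsort(-s, kind="stable")
    y = labels[order]
    s_sorted = s[order]
    boundary = np.flatnonzero(np.diff(s_sorted) != 0)
    ends = np.r_[boundary, s.size - 1]
    tps = np.cumsum(y == 1)[ends]
    fps = np.cumsum(y == 0)[ends]
    points = np.column_stack([fps / n_neg, tps / n_pos])
    return np.vstack([[0.0, 0.0], points])


def auc(points: np.ndarray) -> float:
    """Trapezoidal area under an ROC point sequence."""
    points = np.asarray(points, dtype=float)
    return float(np.trapezoid(points[:, 1], points[:, 0]))


# ---------------------------------------------------------------------------
# Model orchestration


def make_model(name: str, **params):
    """Instantiate a classifier by short name: tree | knn | kernel | hpf."""
    makers = {
        "tree": GiniTreeClassifier,
        "knn": DistanceWeightedKNNClassifier,
        "kernel": RandomFeatureKernelLogistic,
        "hpf": HPFThresholdClassifier,
    }
    if name not in makers:
        raise ConfigurationError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    return makers[name](**params)


def design_matrix(table: pd.DataFrame, model_name: str) -> np.ndarray:
    """Feature matrix for a model: the five densitometry columns, or the
    single HPF score column for the threshold model."""
    if model_name == "hpf":
        return hpf_scores(table).reshape(-1, 1)
    return table[FEATURE_COLUMNS].to_numpy(float)


def model_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous scores oriented so higher favours the positive class."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, -1]
    return model.decision_function(X)


def _labels(table: pd.DataFrame) -> np.ndarray:
    if "rili" not in table.columns or table["rili"].isna().any():
        raise ConfigurationError("evaluation needs a fully labelled 'rili' column")
    return table["rili"].to_numpy(int)


def cross_validate(
    model_spec: str | tuple[str, dict],
    table: pd.DataFrame,
    plan: SplitPlan | None = None,
    k: int = 5,
    seed: int = 0,
) -> EvalResult:
    """Stratified k-fold CV plus resubstitution and a pooled out-of-fold ROC.

    A fold whose training half degenerates (e.g. a single class for the
    kernel model) is recorded as a failure: excluded from the mean with a
    warning rather than aborting the run.
    """
    name, params = (model_spec, {}) if isinstance(model_spec, str) else model_spec
    y = _labels(table)
    X = design_matrix(table, name)
    if plan is None:
        plan = stratified_kfold(y, k=k, seed=seed)

    resub_model = make_model(name, **params).fit(X, y)
    result = EvalResult(resubstitution_accuracy=accuracy(resub_model.predict(X), y))

    oof_scores = np.full(y.size, np.nan)
    for fold in range(plan.k):
        train_idx, test_idx = plan.fold_indices(fold)
        try:
            m = make_model(name, **params).fit(X[train_idx], y[train_idx])
        except ValueError as exc:
            warnings.warn(f"fold {fold} failed and is excluded: {exc}", stacklevel=2)
            continue
        result.cv_fold_accuracies.append(accuracy(m.predict(X[test_idx]), y[test_idx]))
        oof_scores[test_idx] = model_scores(m, X[test_idx])
    if result.cv_fold_accuracies:
        result.cv_accuracy = float(np.mean(result.cv_fold_accuracies))
    scored = np.isfinite(oof_scores)
    if scored.any() and np.unique(y[scored]).size == 2:
        result.roc_points = roc_curve(oof_scores[scored], y[scored])
        result.auc = auc(result.roc_points)
    return result


def evaluate_holdout(
    model_spec: str | tuple[str, dict], train: pd.DataFrame, test: pd.DataFrame
) -> float:
    """Accuracy (%) of a model fitted on ``train`` and scored on ``test``."""
    name, params = (model_spec, {}) if isinstance(model_spec, str) else model_spec
    model = make_model(name, **params).fit(design_matrix(train, name), _labels(train))
    return accuracy(model.predict(design_matrix(test, name)), _labels(test))


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass
class PipelineConfig:
    """Everything the end-to-end runner needs.

    ``cv_on_train_partition`` controls whether the 5-fold CV runs inside
    the training partition (default) or over the full table — the
    published setup is ambiguous on this point, so it is a parameter.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    features_csv: str | None = None
    models: tuple[str, ...] = MODEL_NAMES
    model_params: dict[str, dict] = field(default_factory=dict)
    k_folds: int = 5
    n_train: int = 159
    seed: int = 0
    cv_on_train_partition: bool = True


_SUMMARY_FEATURES_HU = ["hu_min", "hu_max", "hu_mean", "hu_sd"]


def _comparison_row(table: pd.DataFrame, feature: str, values: np.ndarray | None = None):
    if values is None:
        comp = cohort_stats.compare_feature(table, feature)
    else:
        y = _labels(table)
        comp = cohort_stats.mann_whitney_u(values[y == 0], values[y == 1])
    rows = []
    for status, d in (("No", comp.group1), ("Yes", comp.group2)):
        rows.append(
            {
                "parameter": feature,
                "rili": status,
                "mean": round(d.mean, 2),
                "sd": round(d.sd, 2),
                "median": round(d.median, 2),
                "min": round(d.min, 2),
                "max": round(d.max, 2),
                "p_value": round(comp.p_two_sided, 3),
                "effect_r": round(comp.effect_r, 2),
            }
        )
    return rows


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Simulate/load -> HPF scoring -> comparisons -> train -> evaluate.

    Returns a JSON-serialisable report with cohort, HU-summary, volume/HPF
    summary and per-model accuracy sections. Deterministic: identical
    config (including seeds) yields byte-identical serialised reports.
    """
    if config.features_csv is not None:
        from .features import read_feature_table

        table = read_feature_table(config.features_csv)
    else:
        table = sample_feature_table(config.cohort)
    if len(table) == 0:
        raise ConfigurationError("empty feature table: nothing to run")
    y = _labels(table)
    if np.unique(y).size < 2:
        raise ConfigurationError("pipeline needs both RILI groups present")

    n = len(table)
    n_rili = int((y == 1).sum())
    report: dict[str, Any] = {
        "cohort": {
            "n": n,
            "n_rili": n_rili,
            "n_no_rili": n - n_rili,
            "rili_prevalence_percent": round(100.0 * n_rili / n, 1),
            "seed": config.seed,
        }
    }

    report["hu_summary"] = [
        row for f in _SUMMARY_FEATURES_HU for row in _comparison_row(table, f)
    ]
    scores = hpf_scores(table)
    report["volume_hpf_summary"] = _comparison_row(table, "volume_cm3") + [
        {**row, "parameter": "hpf"}
        for row in _comparison_row(table, "hpf", values=scores)
    ]

    train, test = holdout_split(table, n_train=config.n_train, seed=config.seed)
    cv_table = train if config.cv_on_train_partition else table
    models_section = {}
    for name in config.models:
        params = dict(config.model_params.get(name, {}))
        if name == "kernel":
            params.setdefault("random_state", config.seed)
        res = cross_validate((name, params), cv_table, k=config.k_folds, seed=config.seed)
        res.holdout_accuracy = evaluate_holdout((name, params), train, test)
        d = res.to_dict()
        d["resubstitution_accuracy"] = round(d["resubstitution_accuracy"], 1)
        d["cv_accuracy"] = round(d["cv_accuracy"], 1)
        d["cv_fold_accuracies"] = [round(a, 1) for a in d["cv_fold_accuracies"]]
        d["holdout_accuracy"] = round(d["holdout_accuracy"], 1)
        d["auc"] = round(d["auc"], 3) if np.isfinite(d["auc"]) else None
        models_section[name] = d
    report["models"] = models_section
    report["split"] = {"n_train": len(train), "n_test": len(test), "k_folds": config.k_folds}
    return report


def report_to_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def report_to_csvs(report: dict, out_dir: str | Path) -> list[Path]:
    """Write the three table-shaped report sections as CSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for key, fname in (
        ("hu_summary", "hu_summary.csv"),
        ("volume_hpf_summary", "volume_hpf_summary.csv"),
    ):
        path = out_dir / fname
        pd.DataFrame(report[key]).to_csv(path, index=False)
        written.append(path)
    rows = [
        {
            "model": name,
            "accuracy_valid_percent": d["cv_accuracy"],
            "accuracy_test_percent": d["resubstitution_accuracy"],
            "holdout_accuracy_percent": d["holdout_accuracy"],
            "auc": d["auc"],
        }
        for name, d in report["models"].items()
    ]
    path = out_dir / "model_accuracy.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    written.append(path)
    return written
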