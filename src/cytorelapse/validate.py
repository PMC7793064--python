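"""Performance estimation for the control-point classifier.

Implements the full validation harness used to judge whether the planted (or
real) class differences carry predictive signal:

* repeated stratified K-fold and leave-one-out cross-validation with feature
  selection strictly inside each training fold (no leakage);
* confusion-matrix metrics (accuracy, sensitivity, specificity, PPV, NPV)
  and trapezoidal ROC/AUC with relapse (R) as the positive class;
* Monte-Carlo feature-frequency analysis over random 75:25 splits;
* a Random-Forest comparison (out-of-bag error, permutation importance
  aggregated to marker level);
* two-sample t-tests on per-patient summary statistics and fitted curve
  parameters.

Fold assignment is stratified by class, and every training portion must
contain at least two patients per class (otherwise the within-class sigma of
the Fisher model is undefined); offending random draws are redrawn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .fisher import FisherModel, classify, fisher_matrix
from .profiles import PercentileMatrix

__all__ = [
    "confusion_metrics", "PerformanceReport", "cross_validate",
    "FeatureFrequencyResult", "feature_frequency",
    "RandomForestReport", "random_forest_comparison", "compare_summaries",
]

METRICS = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "auc")


def confusion_metrics(y_true, y_pred, scores=None) -> dict[str, float]:
    """Confusion-matrix metrics with R as the positive class.

    PPV/NPV are NaN when nothing is predicted positive/negative.  AUC uses
    the trapezoidal (mid-rank ties) convention and requires ``scores``.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("truth and prediction lists must have equal length")
    if not {"R", "N"} <= set(y_true):
        raise ValueError("both classes must be present in the truth labels")
    tp = sum(t == "R" and p == "R" for t, p in zip(y_true, y_pred))
    tn = sum(t == "N" and p == "N" for t, p in zip(y_true, y_pred))
    fp = sum(t == "N" and p == "R" for t, p in zip(y_true, y_pred))
    fn = sum(t == "R" and p == "N" for t, p in zip(y_true, y_pred))
    out = {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "accuracy": (tp + tn) / len(y_true),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
    }
    if scores is not None:
        out["auc"] = float(roc_auc_score([1 if t == "R" else 0 for t in y_true],
                                         list(scores)))
    return out


@dataclass
class PerformanceReport:
    """Mean +/- sd of the validation metrics over repeated CV runs."""

    scheme: str
    k: int | None
    repeats: int
    seed: int
    per_repeat: pd.DataFrame            # one row per repeat, METRICS columns + counts
    n_patients: int = 0

    @property
    def mean(self) -> pd.Series:
        return self.per_repeat[list(METRICS)].mean()

    @property
    def sd(self) -> pd.Series:
        return self.per_repeat[list(METRICS)].std(ddof=1).fillna(0.0)

    def summary_row(self) -> dict[str, str]:
        label = "LOOCV" if self.scheme == "loocv" else f"{self.k}-Fold"
        row = {"method": label}
        for m in METRICS:
            row[m] = f"{self.mean[m]:.2f} ± {self.sd[m]:.2f}"
        return row


def _class_counts(labels: np.ndarray) -> tuple[int, int]:
    return int((labels == "R").sum()), int((labels == "N").sum())


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator,
                      max_attempts: int = 100) -> list[np.ndarray]:
    """Stratified fold test-index sets whose complements keep >=2 per class."""
    for _ in range(max_attempts):
        state = int(rng.integers(2**31 - 1))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=state)
        folds = [test for _, test in skf.split(np.zeros(len(labels)), labels)]
        ok = True
        for test in folds:
            train_labels = np.delete(labels, test)
            n_r, n_n = _class_counts(train_labels)
            if n_r < 2 or n_n < 2:
                ok = False
                break
        if ok:
            return folds
    raise ValueError("could not draw stratified folds with >=2 patients per class in training")


def cross_validate(cohort: list[PercentileMatrix], scheme: str = "loocv",
                   k: int | None = None, repeats: int = 20, seed: int = 0,
                   threshold: float = 0.5, location: str = "median",
                   convention: str = "proximity", distance: str = "feature") -> PerformanceReport:
    """Repeated cross-validation of the Fisher's-Ratio classifier.

    Feature selection and model fitting happen inside each training fold
    only.  Out-of-fold predictions are pooled per repeat; the report carries
    the mean and sd of each metric across repeats.  LOOCV folds are
    deterministic, so its repeats differ only if the classifier itself had
    random components; the sd is then zero by construction.
    """
    labels = np.array([pm.label for pm in cohort])
    n = len(cohort)
    n_r, n_n = _class_counts(labels)
    if scheme not in ("loocv", "kfold"):
        raise ValueError("scheme must be 'loocv' or 'kfold'")
    if scheme == "kfold":
        if k is None or k < 2:
            raise ValueError("k-fold validation needs k >= 2")
        if k > min(n_r, n_n):
            raise ValueError(
                f"k={k} exceeds the smaller class size {min(n_r, n_n)}; the fold "
                "count is capped by the number of relapsing patients"
            )
    if min(n_r, n_n) < 3:
        raise ValueError("need at least 3 patients per class so every training fold keeps 2")

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(repeats):
        if scheme == "loocv":
            folds = [np.array([i]) for i in range(n)]
        else:
            folds = _stratified_folds(labels, k, rng)
        y_true, y_pred, scores = [], [], []
        for test_idx in folds:
            train = [cohort[i] for i in range(n) if i not in set(test_idx)]
            with warnings.catch_warnings():
                # per-fold refits re-emit the zero-variance drop warning
                warnings.simplefilter("ignore", UserWarning)
                model = fisher_matrix(train, threshold=threshold, location=location)
            for i in test_idx:
                pred = classify(cohort[i], model, convention=convention, distance=distance)
                y_true.append(labels[i])
                y_pred.append(pred.label)
                scores.append(pred.p_relapse)
        rows.append(confusion_metrics(y_true, y_pred, scores))
    return PerformanceReport(scheme=scheme, k=k, repeats=repeats, seed=seed,
                             per_repeat=pd.DataFrame(rows), n_patients=n)


@dataclass
class FeatureFrequencyResult:
    """Marker usage frequencies across random-split classifiers."""

    accuracies: np.ndarray                       # per split
    selected_markers: list[list[str]]            # per split
    tables: dict[float, dict[str, float]]        # threshold -> marker -> freq
    n_splits: int
    train_fraction: float
    seed: int

    def qualifying(self, threshold: float) -> list[int]:
        return [i for i, a in enumerate(self.accuracies) if a >= threshold]


def _split_indices(labels: np.ndarray, train_fraction: float,
                   rng: np.random.Generator, max_attempts: int = 100) -> np.ndarray:
    n = len(labels)
    n_train = int(round(train_fraction * n))
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        train = perm[:n_train]
        n_r, n_n = _class_counts(labels[train])
        t_r, t_n = _class_counts(labels[perm[n_train:]])
        if n_r >= 2 and n_n >= 2 and t_r >= 1 and t_n >= 1:
            return train
    raise ValueError("could not draw a split with both classes represented")


def feature_frequency(cohort: list[PercentileMatrix], n_splits: int = 100,
                      train_fraction: float = 0.75,
                      accuracy_thresholds=(0.0, 0.5, 0.6, 0.7, 0.8),
                      seed: int = 0, threshold: float = 0.5,
                      location: str = "median", convention: str = "proximity",
                      distance: str = "feature") -> FeatureFrequencyResult:
    """Marker usage frequency over ``n_splits`` random train/test splits.

    For each split a classifier is fitted on the training portion and scored
    on the held-out portion; for each accuracy threshold the table reports,
    over the qualifying classifiers (test accuracy >= threshold), the
    fraction that used each marker.
    """
    labels = np.array([pm.label for pm in cohort])
    markers = cohort[0].markers
    n = len(cohort)
    rng = np.random.default_rng(seed)
    accuracies, used = [], []
    for _ in range(n_splits):
        train_idx = set(_split_indices(labels, train_fraction, rng))
        train = [cohort[i] for i in range(n) if i in train_idx]
        test = [cohort[i] for i in range(n) if i not in train_idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = fisher_matrix(train, threshold=threshold, location=location)
        preds = [classify(pm, model, convention=convention, distance=distance)
                 for pm in test]
        correct = sum(p.label == pm.label for p, pm in zip(preds, test))
        accuracies.append(correct / len(test))
        used.append(model.selected_markers)

    accuracies = np.array(accuracies)
    tables: dict[float, dict[str, float]] = {}
    for thr in accuracy_thresholds:
        qual = [u for a, u in zip(accuracies, used) if a >= thr]
        if not qual:
            warnings.warn(f"no classifier reaches accuracy threshold {thr}")
            tables[float(thr)] = {}
            continue
        tables[float(thr)] = {m: sum(m in u for u in qual) / len(qual) for m in markers}
    return FeatureFrequencyResult(accuracies=accuracies, selected_markers=used,
                                  tables=tables, n_splits=n_splits,
                                  train_fraction=train_fraction, seed=seed)


@dataclass
class RandomForestReport:
    """Out-of-bag error trace and marker-level permutation importance."""

    oob_errors: np.ndarray
    importance: pd.DataFrame       # rows: markers; columns: mean, sd, top_fraction
    n_runs: int
    n_trees: int
    seed: int

    @property
    def mean_oob_error(self) -> float:
        return float(self.oob_errors.mean())

    @property
    def sd_oob_error(self) -> float:
        return float(self.oob_errors.std(ddof=1))


def _group_permutation_importance(forest, x_test, y_test, m: int, p: int,
                                  n_repeats: int, rng: np.random.Generator) -> np.ndarray:
    """Marker-level permutation importance: a marker's percentile columns are
    permuted *jointly* (same row shuffle for the whole block).

    Permuting the columns one at a time tells a forest nothing here — a
    marker's percentile levels are strongly correlated, so the remaining
    levels stand in for a single shuffled one and every per-column importance
    collapses to zero; shuffling the block as a unit measures the marker's
    actual contribution.
    """
    baseline = forest.score(x_test, y_test)
    imp = np.zeros(m)
    for j in range(m):
        cols = slice(j * p, (j + 1) * p)
        drops = []
        for _ in range(n_repeats):
            xp = x_test.copy()
            xp[:, cols] = xp[rng.permutation(len(xp)), cols]
            drops.append(baseline - forest.score(xp, y_test))
        imp[j] = np.mean(drops)
    return imp


def random_forest_comparison(cohort: list[PercentileMatrix], n_runs: int = 100,
                             n_trees: int = 50, train_fraction: float = 0.75,
                             seed: int = 0, n_permutation_repeats: int = 3,
                             importance: str = "group",
                             aggregate: str = "sum") -> RandomForestReport:
    """Random-Forest benchmark on the flattened percentile features.

    Per run: a stratified 75:25 split, a forest of ``n_trees`` with bootstrap
    out-of-bag scoring on the training portion, and permutation importance on
    the held-out portion.  ``importance='group'`` (default) permutes each
    marker's percentile block jointly; ``importance='column'`` permutes
    single percentile columns and aggregates to marker level (``sum``
    preserves total importance; ``max`` is available) — with strongly
    correlated percentile levels the column mode underestimates badly.
    """
    if aggregate not in ("sum", "max"):
        raise ValueError("aggregate must be 'sum' or 'max'")
    if importance not in ("group", "column"):
        raise ValueError("importance must be 'group' or 'column'")
    markers = cohort[0].markers
    m, p = cohort[0].values.shape
    x = np.stack([pm.values.ravel() for pm in cohort])
    y = np.array([pm.label for pm in cohort])
    rng = np.random.default_rng(seed)

    oob, per_run_imp = [], []
    agg = np.sum if aggregate == "sum" else np.max
    for _ in range(n_runs):
        train = _split_indices(y, train_fraction, rng)
        test = np.setdiff1d(np.arange(len(y)), train)
        state = int(rng.integers(2**31 - 1))
        forest = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                        bootstrap=True, random_state=state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)   # OOB on tiny samples
            forest.fit(x[train], y[train])
        oob.append(1.0 - forest.oob_score_)
        if importance == "group":
            per_run_imp.append(_group_permutation_importance(
                forest, x[test], y[test], m, p, n_permutation_repeats, rng))
        else:
            imp = permutation_importance(forest, x[test], y[test],
                                         n_repeats=n_permutation_repeats,
                                         random_state=state)
            per_run_imp.append(agg(imp.importances_mean.reshape(m, p), axis=1))

    imp_runs = np.stack(per_run_imp)                      # (runs, markers)
    top = np.argmax(imp_runs, axis=1)
    importance = pd.DataFrame({
        "marker": markers,
        "importance_mean": imp_runs.mean(axis=0),
        "importance_sd": imp_runs.std(axis=0, ddof=1),
        "top_fraction": np.bincount(top, minlength=m) / n_runs,
    }).set_index("marker")
    return RandomForestReport(oob_errors=np.array(oob), importance=importance,
                              n_runs=n_runs, n_trees=n_trees, seed=seed)


def compare_summaries(stats_table: pd.DataFrame, equal_var: bool = True,
                      alpha_level: float = 0.05) -> pd.DataFrame:
    """Two-sample t-tests of per-patient marker statistics between classes.

    ``stats_table`` is tidy: one row per (patient, marker) with a ``label``
    column and one column per statistic (median / mean / sd, optionally the
    fitted curve parameters alpha / gamma).  Each statistic of each marker is
    compared between R and N patients; flags mark p below ``alpha_level``
    with no multiplicity correction.  Statistics with zero variance in both
    classes are skipped with a note.
    """
    id_cols = {"patient_id", "label", "marker"}
    stat_cols = [c for c in stats_table.columns if c not in id_cols]
    rows = []
    for marker, sub in stats_table.groupby("marker", sort=True):
        r = sub[sub["label"] == "R"]
        n = sub[sub["label"] == "N"]
        if len(r) < 2 or len(n) < 2:
            raise ValueError(f"marker {marker!r}: need >=2 patients per class")
        for col in stat_cols:
            a, b = r[col].dropna().to_numpy(), n[col].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2 or (a.var(ddof=1) == 0 and b.var(ddof=1) == 0):
                rows.append({"marker": marker, "statistic": col, "t": np.nan,
                             "p": np.nan, "significant": False,
                             "note": "skipped: zero variance or too few values"})
                continue
            t, pval = stats.ttest_ind(a, b, equal_var=equal_var)
            rows.append({"marker": marker, "statistic": col, "t": float(t),
                         "p": float(pval), "significant": bool(pval < alpha_level),
                         "note": ""})
    return pd.DataFrame(rows)
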