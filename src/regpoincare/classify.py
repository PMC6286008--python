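"""Relief feature weighting and leave-one-out apnea/baseline classification.

Four classifiers are compared — logistic regression (binomial, effectively
unpenalised), Gaussian naive Bayes, a linear-kernel SVM (C = 1) and a CART
decision tree (Gini, minimum leaf size 3) — each trained on every admissible
combination of the lag-resolved Poincaré descriptors {SDratio, R, CCM} at
every lag, and validated with the leave-one-out strategy.  Because SDratio
and R are near-duplicates (strongly correlated), combinations containing
both are excluded.  Per (classifier, combination, lag), accuracy is the
fraction of correctly classified held-out segments and AUC is computed from
the pooled held-out scores.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ClassError, ConfigurationError
from .group_stats import POSITIVE_CLASS

CLASSIFIER_KINDS = ("logistic", "naive_bayes", "svm_linear", "cart")
SELECTED_FEATURES = ("SDratio", "R", "CCM")

#: Table-style reporting thresholds: AUC > 0.8 and accuracy >= 80%.
FLAG_AUC = 0.8
FLAG_ACCURACY = 0.80


@dataclass(frozen=True)
class InputCombo:
    """A feature subset and lag used as classifier input."""

    feature_names: tuple[str, ...]
    tau: int

    def __post_init__(self) -> None:
        names = tuple(self.feature_names)
        object.__setattr__(self, "feature_names", names)
        if not names:
            raise ConfigurationError("combo needs at least one feature")
        if "SDratio" in names and "R" in names:
            raise ConfigurationError(
                "SDratio and R are strongly correlated; their combination is excluded"
            )


@dataclass(frozen=True)
class ClassifierReport:
    classifier: str
    combo: InputCombo
    auc: float
    accuracy: float
    predictions: pd.DataFrame = field(repr=False, compare=False)


def enumerate_combos(tau: int, features=SELECTED_FEATURES) -> list[InputCombo]:
    """All admissible feature subsets at one lag (5 for the default trio)."""
    combos = []
    for k in range(1, len(features) + 1):
        for subset in itertools.combinations(features, k):
            if "SDratio" in subset and "R" in subset:
                continue
            combos.append(InputCombo(feature_names=subset, tau=tau))
    return combos


def relief_weights(feature_matrix, labels) -> np.ndarray:
    """Classic Relief weights (one per feature).

    Features are min-max scaled to [0, 1]; for each sample the nearest hit
    (same class) and nearest miss (other class) are found by Euclidean
    distance, and each feature accumulates |x_f - miss_f| - |x_f - hit_f|,
    averaged over all samples.  Positive weights mark features that separate
    the classes better than they scatter within a class.
    """
    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or not np.all(np.isfinite(X)):
        raise ConfigurationError("feature matrix must be 2-D and finite")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ClassError("need at least 2 samples in each of 2 classes")

    span = np.ptp(X, axis=0)
    span[span == 0] = 1.0
    Xs = (X - X.min(axis=0)) / span

    n = Xs.shape[0]
    d2 = np.sum((Xs[:, None, :] - Xs[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)
    w = np.zeros(Xs.shape[1])
    for i in range(n):
        same = y == y[i]
        same[i] = False
        hit = np.argmin(np.where(same, d2[i], np.inf))
        miss = np.argmin(np.where(~same, d2[i], np.inf))
        w += np.abs(Xs[i] - Xs[miss]) - np.abs(Xs[i] - Xs[hit])
    return w / n


def _make_classifier(kind: str, seed: int):
    if kind == "logistic":
        # unpenalised binomial logistic fit
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    if kind == "naive_bayes":
        return GaussianNB()
    if kind == "svm_linear":
        # C = 1 is meaningful only on standardized inputs; the scaler is
        # fit inside each training fold.
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    if kind == "cart":
        return DecisionTreeClassifier(
            criterion="gini", min_samples_leaf=3, random_state=seed
        )
    raise ConfigurationError(f"unknown classifier kind {kind!r}")


def _combo_matrix(combo: InputCombo, feature_table: pd.DataFrame):
    chunk = feature_table.loc[feature_table["tau"] == combo.tau]
    sub = chunk[["segment_id", "label", *combo.feature_names]].dropna()
    X = sub[list(combo.feature_names)].to_numpy(dtype=float)
    y = (sub["label"] == POSITIVE_CLASS).to_numpy(dtype=int)
    return X, y, sub["segment_id"].to_numpy()


def _held_out_score(model, xi: np.ndarray, X_train: np.ndarray) -> tuple[float, float]:
    """(raw score, fold-centred score) for the held-out sample.

    Pooling raw leave-one-out scores biases the AUC downward: the held-out
    sample's class is underrepresented in its own training fold, shifting
    every score against the true label.  Centring each score by the training
    fold's mean self-predicted score removes that per-fold shift, so the
    pooled AUC is chance-level (0.5) under label permutation.
    """
    if hasattr(model, "predict_proba"):
        raw = float(model.predict_proba(xi)[0, 1])
        center = float(model.predict_proba(X_train)[:, 1].mean())
    else:
        raw = float(model.decision_function(xi)[0])
        center = float(model.decision_function(X_train).mean())
    return raw, raw - center


def loocv_evaluate(
    classifier_kind: str,
    combo: InputCombo,
    feature_table: pd.DataFrame,
    seed: int = 0,
) -> ClassifierReport:
    """Leave-one-out evaluation of one classifier on one input combination.

    Probability scores are thresholded at 0.5 and decision values at 0 for
    accuracy; AUC is computed from the pooled fold-centred held-out scores
    (see :func:`_held_out_score`).  Degenerate training folds (a single
    class) are skipped with a warning.
    """
    X, y, seg_ids = _combo_matrix(combo, feature_table)
    if np.unique(y).size < 2 or min(np.bincount(y)) < 2:
        raise ClassError("need at least 2 segments per class")

    n = len(y)
    scores = np.full(n, np.nan)
    centred = np.full(n, np.nan)
    preds = np.full(n, -1)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.unique(y[mask]).size < 2:
            warnings.warn(f"fold {i}: single-class training set skipped")
            continue
        model = _make_classifier(classifier_kind, seed)
        model.fit(X[mask], y[mask])
        raw, cen = _held_out_score(model, X[i : i + 1], X[mask])
        scores[i] = raw
        centred[i] = cen
        cut = 0.5 if hasattr(model, "predict_proba") else 0.0
        preds[i] = int(raw > cut)

    valid = ~np.isnan(scores)
    auc = float(roc_auc_score(y[valid], centred[valid]))
    accuracy = float(np.mean(preds[valid] == y[valid]))
    predictions = pd.DataFrame({
        "segment_id": seg_ids, "y_true": y, "score": scores, "y_pred": preds,
    })
    return ClassifierReport(
        classifier=classifier_kind, combo=combo, auc=auc, accuracy=accuracy,
        predictions=predictions,
    )


def model_search(
    feature_table: pd.DataFrame,
    tau_values=None,
    classifiers=CLASSIFIER_KINDS,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate every classifier x feature-combination x lag.

    Returns one row per evaluation with ``flagged`` marking AUC > 0.8 and
    accuracy >= 0.80.  Use :func:`summarize_flagged` for the Table-style
    contiguous-lag-range summary.
    """
    if tau_values is None:
        tau_values = sorted(feature_table["tau"].unique())
    rows = []
    for tau in tau_values:
        for combo in enumerate_combos(int(tau)):
            for kind in classifiers:
                rep = loocv_evaluate(kind, combo, feature_table, seed=seed)
                rows.append({
                    "classifier": kind,
                    "inputs": "+".join(combo.feature_names),
                    "tau": int(tau),
                    "auc": rep.auc,
                    "accuracy": rep.accuracy,
                    "flagged": rep.auc > FLAG_AUC and rep.accuracy >= FLAG_ACCURACY,
                })
    return pd.DataFrame(rows)


def summarize_flagged(reports: pd.DataFrame) -> pd.DataFrame:
    """Group flagged evaluations into contiguous lag ranges.

    For each (classifier, inputs) pair, contiguous runs of flagged lags are
    merged into one row with the lag range and mean +/- sd of AUC and
    accuracy over the run.
    """
    flagged = reports.loc[reports["flagged"]].sort_values(["classifier", "inputs", "tau"])
    rows = []
    for (clf, inputs), grp in flagged.groupby(["classifier", "inputs"]):
        taus = grp["tau"].to_numpy()
        run_start = 0
        breaks = np.nonzero(np.diff(taus) != 1)[0]
        for end in [*breaks, len(taus) - 1]:
            run = grp.iloc[run_start : end + 1]
            rows.append({
                "classifier": clf,
                "inputs": inputs,
                "tau_min": int(run["tau"].min()),
                "tau_max": int(run["tau"].max()),
                "auc_mean": run["auc"].mean(),
                "auc_sd": run["auc"].std(ddof=0),
                "acc_mean": run["accuracy"].mean(),
                "acc_sd": run["accuracy"].std(ddof=0),
            })
            run_start = end + 1
    return pd.DataFrame(rows)
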