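"""Hypothesis testing, ROC analysis and pooled feature correlations.

Group comparisons use a normality-gated two-sample test: when both groups
pass a Kolmogorov-Smirnov normality screen with estimated parameters
(Lilliefors correction) at alpha = 0.05, a Welch t-test is used; otherwise
the two-sided Mann-Whitney U test.  Significance is reported at the
unadjusted 0.05 level and at the Bonferroni-corrected 0.025 level (two
feature families compared).

Single-feature discrimination is summarised by the rank-formulation AUC
(oriented so AUC >= 0.5, with the direction recorded) and by sensitivity,
specificity and accuracy at the Youden-optimal operating point, with apnea
as the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .errors import ClassError, InsufficientDataError

ALPHA_NORMALITY = 0.05
ALPHA_UNADJUSTED = 0.05
ALPHA_BONFERRONI = 0.025
POSITIVE_CLASS = "apnea"


@dataclass(frozen=True)
class GroupComparison:
    p_value: float
    test_used: str  # "t" (Welch) or "mann_whitney"
    significant_unadjusted: bool
    significant_bonferroni: bool
    median_a: float
    iqr_a: float
    median_b: float
    iqr_b: float
    feature_name: str | None = None
    tau: int | None = None


@dataclass(frozen=True)
class RocSummary:
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    direction: str  # "greater-is-apnea" or "lesser-is-apnea"
    feature_name: str | None = None
    tau: int | None = None


def _is_normal(values: np.ndarray) -> bool:
    # Lilliefors needs >= 4 observations; tiny or constant groups go to the
    # rank test.
    if values.size < 4 or np.ptp(values) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = lilliefors(values, dist="norm")
    return p > ALPHA_NORMALITY


def compare_groups(values_a, values_b, feature_name=None, tau=None) -> GroupComparison:
    """Normality-gated two-sample comparison (Welch t or Mann-Whitney)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("need at least 3 values per group")

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("degenerate input: all values tied; p set to 1")
        p, test = 1.0, "mann_whitney"
    elif _is_normal(a) and _is_normal(b):
        _, p = stats.ttest_ind(a, b, equal_var=False)
        test = "t"
    else:
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney"
    p = float(p)
    return GroupComparison(
        p_value=p,
        test_used=test,
        significant_unadjusted=p < ALPHA_UNADJUSTED,
        significant_bonferroni=p < ALPHA_BONFERRONI,
        median_a=float(np.median(a)),
        iqr_a=float(stats.iqr(a)),
        median_b=float(np.median(b)),
        iqr_b=float(stats.iqr(b)),
        feature_name=feature_name,
        tau=tau,
    )


def roc_analysis(values, labels, feature_name=None, tau=None) -> RocSummary:
    """Single-feature ROC with apnea as the positive class.

    AUC from the Mann-Whitney rank formulation, oriented so AUC >= 0.5;
    the operating point maximises Youden's J (sensitivity + specificity - 1).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray([1 if lab == POSITIVE_CLASS else 0 for lab in labels])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ClassError("both classes must be present")

    # Rank (Mann-Whitney) AUC: P(score_pos > score_neg) + 0.5 P(tie).
    ranks = stats.rankdata(v)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    direction = "greater-is-apnea"
    scores = v
    if auc < 0.5:
        auc = 1.0 - auc
        direction = "lesser-is-apnea"
        scores = -v

    # Youden-optimal threshold over the midpoints between sorted scores.
    order = np.argsort(scores)
    s_sorted, y_sorted = scores[order], y[order]
    cut_candidates = np.concatenate(
        [[s_sorted[0] - 1.0], (s_sorted[1:] + s_sorted[:-1]) / 2.0, [s_sorted[-1] + 1.0]]
    )
    best = None
    for thr in cut_candidates:
        pred = scores > thr
        sens = float(pred[y == 1].mean())
        spec = float((~pred)[y == 0].mean())
        j = sens + spec - 1.0
        if best is None or j > best[0]:
            best = (j, thr, sens, spec)
    _, thr, sens, spec = best
    acc = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)
    # Report the threshold on the original feature scale.
    thr_orig = thr if direction == "greater-is-apnea" else -thr
    return RocSummary(
        auc=float(auc), sensitivity=sens, specificity=spec, accuracy=float(acc),
        threshold=float(thr_orig), direction=direction,
        feature_name=feature_name, tau=tau,
    )


def group_comparison_sweep(feature_table: pd.DataFrame,
                           features=("SD1", "SD2", "SDarea", "SDratio", "R", "CCM"),
                           ) -> pd.DataFrame:
    """Per-feature, per-tau apnea-vs-baseline comparison and ROC summary.

    ``feature_table`` is the long-format sweep of
    :func:`regpoincare.poincare.feature_sweep` (columns segment_id, label,
    tau, features).  Rows with missing values are dropped per feature/tau.
    """
    rows = []
    for tau, chunk in feature_table.groupby("tau"):
        for feat in features:
            sub = chunk[["label", feat]].dropna()
            a = sub.loc[sub["label"] == "apnea", feat].to_numpy()
            b = sub.loc[sub["label"] == "baseline", feat].to_numpy()
            if a.size < 3 or b.size < 3:
                continue
            cmp = compare_groups(a, b, feature_name=feat, tau=int(tau))
            roc = roc_analysis(
                sub[feat].to_numpy(), sub["label"].to_numpy(),
                feature_name=feat, tau=int(tau),
            )
            rows.append({
                "feature": feat, "tau": int(tau), "p": cmp.p_value,
                "test": cmp.test_used,
                "significant_0.05": cmp.significant_unadjusted,
                "significant_0.025": cmp.significant_bonferroni,
                "auc": roc.auc, "sens": roc.sensitivity, "spec": roc.specificity,
                "accuracy": roc.accuracy, "direction": roc.direction,
            })
    return pd.DataFrame(rows)


def feature_correlations(feature_table: pd.DataFrame,
                         features=("SDratio", "R", "CCM")) -> pd.DataFrame:
    """Pairwise Pearson correlations pooled over all segments and lags.

    Returns the symmetric correlation matrix; ``attrs['p_values']`` and
    ``attrs['n_pairs']`` hold the matching p-value and pairwise-complete
    count matrices, ``attrs['n_rows']`` the pooled row count.
    """
    cols = feature_table[list(features)]
    if len(cols.dropna()) < 3:
        raise InsufficientDataError("need at least 3 complete rows")
    k = len(features)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    npair = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(k):
            pair = cols.iloc[:, [i, j]].dropna()
            npair[i, j] = len(pair)
            if i != j:
                r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
                rho[i, j], pval[i, j] = r, p
    out = pd.DataFrame(rho, index=features, columns=features)
    out.attrs["p_values"] = pd.DataFrame(pval, index=features, columns=features)
    out.attrs["n_pairs"] = pd.DataFrame(npair, index=features, columns=features)
    out.attrs["n_rows"] = int(len(cols))
    return out
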