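"""Relief weighting and leave-one-out classifier evaluation."""

import numpy as np
import pandas as pd
import pytest

from regpoincare.classify import (
    InputCombo, enumerate_combos, loocv_evaluate, model_search,
    relief_weights, summarize_flagged,
)
from regpoincare.errors import ClassError, ConfigurationError


def _table_from_matrix(X, y, tau=1, features=("f0", "f1")):
    """Wrap a plain matrix as the long-format sweep table the API expects."""
    cols = {"segment_id": np.arange(len(y)), "label": np.where(y == 1, "apnea", "baseline"),
            "tau": tau}
    for j, name in enumerate(features[: X.shape[1]]):
        cols[name] = X[:, j]
    return pd.DataFrame(cols)


class TestInputCombo:
    def test_combo_enumeration_excludes_sdratio_r(self):
        combos = enumerate_combos(3)
        names = {c.feature_names for c in combos}
        assert names == {("SDratio",), ("R",), ("CCM",),
                         ("SDratio", "CCM"), ("R", "CCM")}

    def test_sdratio_r_pair_rejected(self):
        with pytest.raises(ConfigurationError):
            InputCombo(feature_names=("SDratio", "R"), tau=1)

    def test_empty_combo_rejected(self):
        with pytest.raises(ConfigurationError):
            InputCombo(feature_names=(), tau=1)


class TestReliefWeights:
    def test_constant_feature_has_zero_weight(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.full(20, 0.3), rng.normal(size=20)])
        y = np.array([0, 1] * 10)
        w = relief_weights(X, y)
        assert w[0] == pytest.approx(0.0, abs=1e-12)

    def test_separating_feature_outweighs_noise(self):
        rng = np.random.default_rng(1)
        wins = 0
        for _ in range(100):
            y = np.array([0] * 20 + [1] * 20)
            sep = y + rng.normal(0, 0.05, 40)
            noise = rng.normal(size=40)
            w = relief_weights(np.column_stack([sep, noise]), y)
            wins += w[0] > w[1]
        assert wins >= 95

    def test_null_weights_near_zero(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            X = rng.normal(size=(40, 3))
            y = rng.permutation([0] * 20 + [1] * 20)
            w = relief_weights(X, y)
            assert np.all(np.abs(w) < 0.1)

    def test_single_class_rejected(self):
        with pytest.raises(ClassError):
            relief_weights(np.ones((4, 2)), np.zeros(4))

    def test_relief_prefers_discriminant_poincare_features(self, default_sweep):
        """On the synthetic dataset the regularity descriptors carry the
        class signal, so their Relief weights are positive at small lags."""
        chunk = default_sweep[default_sweep["tau"] == 2]
        X = chunk[["SDratio", "R", "CCM"]].to_numpy()
        y = (chunk["label"] == "apnea").to_numpy(int)
        w = relief_weights(X, y)
        assert np.all(w > 0)


class TestLoocv:
    def test_separable_data_scores_perfectly(self):
        rng = np.random.default_rng(3)
        y = np.array([0] * 10 + [1] * 10)
        X = np.column_stack([y * 2.0 + rng.normal(0, 0.05, 20)])
        table = _table_from_matrix(X, y, features=("SDratio",))
        combo = InputCombo(feature_names=("SDratio",), tau=1)
        for kind in ("logistic", "naive_bayes", "svm_linear", "cart"):
            rep = loocv_evaluate(kind, combo, table)
            assert rep.auc == 1.0 and rep.accuracy == 1.0, kind

    def test_determinism(self, default_sweep):
        combo = InputCombo(feature_names=("SDratio", "CCM"), tau=3)
        a = loocv_evaluate("cart", combo, default_sweep, seed=11)
        b = loocv_evaluate("cart", combo, default_sweep, seed=11)
        assert a.auc == b.auc and a.accuracy == b.accuracy

    def test_permuted_labels_are_chance_level(self, default_sweep):
        rng = np.random.default_rng(4)
        chunk = default_sweep[default_sweep["tau"] == 5].copy()
        aucs = []
        for _ in range(20):
            shuffled = chunk.copy()
            shuffled["label"] = rng.permutation(chunk["label"].to_numpy())
            combo = InputCombo(feature_names=("SDratio",), tau=5)
            try:
                rep = loocv_evaluate("logistic", combo, shuffled)
            except ClassError:
                continue
            aucs.append(rep.auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_cart_reproduces_exhaustive_best_split(self):
        """On a 1-D problem, CART LOO predictions follow the best threshold
        found by brute force over all split points."""
        X = np.array([[0.1], [0.2], [0.3], [0.4], [1.1], [1.2], [1.3], [1.4]])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        # Brute-force: best Gini split anywhere in (0.4, 1.1).
        table = _table_from_matrix(X, y, features=("CCM",))
        rep = loocv_evaluate(
            "cart", InputCombo(feature_names=("CCM",), tau=1), table
        )
        assert rep.accuracy == 1.0 and rep.auc == 1.0


class TestModelSearch:
    def test_flagged_models_on_default_dataset(self, default_sweep):
        """The emulated dataset supports at least one model with AUC > 0.8
        and accuracy >= 80% at a small lag."""
        reports = model_search(default_sweep, tau_values=range(1, 6), seed=0)
        assert len(reports) == 5 * 5 * 4
        flagged = reports[reports["flagged"]]
        assert len(flagged) > 0
        assert flagged["tau"].min() <= 13
        # Moderate, not perfect, separation.
        assert reports["auc"].max() < 0.99

    def test_empty_tau_list(self, default_sweep):
        assert len(model_search(default_sweep, tau_values=[])) == 0

    def test_summary_groups_contiguous_runs(self):
        reports = pd.DataFrame({
            "classifier": ["cart"] * 5, "inputs": ["SDratio"] * 5,
            "tau": [1, 2, 3, 5, 6], "auc": [0.9] * 5, "accuracy": [0.85] * 5,
            "flagged": [True] * 5,
        })
        summary = summarize_flagged(reports)
        assert len(summary) == 2
        assert summary.iloc[0][["tau_min", "tau_max"]].tolist() == [1, 3]
        assert summary.iloc[1][["tau_min", "tau_max"]].tolist() == [5, 6]
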