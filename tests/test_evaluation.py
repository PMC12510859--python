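"""Stability selection, combined models, metrics, calibration, decision curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from deltazone import (
    StabilitySelector,
    calibration_curve,
    classification_metrics,
    decision_curve,
    fit_combined_models,
)
from deltazone.evaluation import youden_threshold


def _candidates(seed=0, n=150):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = pd.DataFrame(
        {
            "signal": y + rng.normal(0, 0.3, n),
            "noise_a": rng.normal(size=n),
            "noise_b": rng.normal(size=n),
            "noise_c": rng.normal(size=n),
        }
    )
    return X, y


class TestStabilitySelector:
    def test_perfect_predictor_ranks_first_everywhere(self):
        X, y = _candidates()
        sel = StabilitySelector(n_folds=5, random_state=0).fit(X, y)
        assert sel.top_k_[0] == "signal"
        assert (sel.ranks_["signal"] == 1.0).all()
        assert sel.mean_rank_["signal"] == 1.0

    def test_candidate_order_invariance_of_selection(self):
        """Permuting candidate columns leaves the selected set unchanged
        and moves aggregate ranks only marginally (learner internals such
        as the network's per-position weight initialization prevent exact
        equality)."""
        X, y = _candidates(3)
        a = StabilitySelector(n_folds=5, random_state=1).fit(X, y)
        b = StabilitySelector(n_folds=5, random_state=1).fit(
            X[list(reversed(X.columns))], y
        )
        assert set(a.top_k_) == set(b.top_k_)
        diff = (a.mean_rank_.sort_index() - b.mean_rank_.sort_index()).abs()
        assert diff.max() < 0.3

    def test_ranks_are_permutations_without_ties(self):
        X, y = _candidates(5)
        sel = StabilitySelector(n_folds=4, random_state=2).fit(X, y)
        for _, row in sel.ranks_.iterrows():
            if row.nunique() == len(row):  # tie-free rows
                assert sorted(row) == [1.0, 2.0, 3.0, 4.0]

    def test_null_candidates_spread_over_top3(self):
        """With pure-noise candidates, no single variable hoards the top-3
        slots across replicates."""
        counts = {f"x{i}": 0 for i in range(5)}
        for s in range(12):
            rng = np.random.default_rng(100 + s)
            X = pd.DataFrame(rng.normal(size=(80, 5)),
                             columns=[f"x{i}" for i in range(5)])
            y = rng.integers(0, 2, 80)
            sel = StabilitySelector(n_folds=3, random_state=s).fit(X, y)
            for v in sel.top_k_:
                counts[v] += 1
        assert max(counts.values()) < 12 * 3 * 0.7  # no candidate dominates

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError, match="2 candidates"):
            StabilitySelector().fit(pd.DataFrame({"a": [1.0, 2.0]}), [0, 1])


class TestCombinedModels:
    def _table(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        rs = rng.normal(size=n)
        loc = rng.integers(0, 2, n)
        nlr = rng.normal(4, 1.5, n)
        eta = -1.0 + 1.4 * rs + 0.9 * loc + 0.4 * (nlr - 4)
        y = (rng.random(n) < expit(eta)).astype(int)
        return pd.DataFrame({"rs": rs, "loc": loc, "nlr": nlr, "rp": y})

    def test_nested_training_auc_nondecreasing(self):
        df = self._table()
        specs = {"m1": ["rs"], "m2": ["rs", "loc"], "m3": ["rs", "loc", "nlr"]}
        models = fit_combined_models(df, specs, n_folds=5)
        aucs = []
        from deltazone import roc_auc
        for name, cols in specs.items():
            p = models[name].predict_proba(df[cols].to_numpy(float))[:, 1]
            aucs.append(roc_auc(p, df["rp"].to_numpy()).auc)
        assert aucs[0] <= aucs[1] + 1e-9 and aucs[1] <= aucs[2] + 1e-9

    def test_pure_noise_covariate_barely_moves_validation_auc(self):
        from deltazone import roc_auc
        deltas = []
        for s in range(25):
            df = self._table(seed=s, n=260)
            train, valid = df.iloc[:180], df.iloc[180:]
            specs = {"base": ["rs", "loc"], "plus": ["rs", "loc", "nlr"]}
            specs["plus"] = ["rs", "loc", "noise"]
            df2 = df.assign(noise=np.random.default_rng(1000 + s).normal(size=len(df)))
            train, valid = df2.iloc[:180], df2.iloc[180:]
            models = fit_combined_models(train, specs, n_folds=5, random_state=s)
            a = {}
            for name, cols in specs.items():
                p = models[name].predict_proba(valid[cols].to_numpy(float))[:, 1]
                a[name] = roc_auc(p, valid["rp"].to_numpy()).auc
            deltas.append(a["plus"] - a["base"])
        assert abs(np.mean(deltas)) < 0.05

    def test_refit_same_seed_identical(self):
        df = self._table(2)
        specs = {"m": ["rs", "loc"]}
        a = fit_combined_models(df, specs, random_state=3)["m"]
        b = fit_combined_models(df, specs, random_state=3)["m"]
        assert np.array_equal(a.coef_, b.coef_) and a.intercept_ == b.intercept_

    def test_singular_design_rejected(self):
        df = self._table(4).assign(dup=lambda d: d["rs"])
        with pytest.raises(ValueError, match="singular"):
            fit_combined_models(df, {"m": ["rs", "dup"]})


class TestClassificationMetrics:
    def test_perfect_probabilities(self):
        y = np.array([0, 0, 1, 1, 1])
        rep = classification_metrics(y.astype(float) * 0.98 + 0.01, y)
        assert (rep.accuracy, rep.sensitivity, rep.specificity) == (1.0, 1.0, 1.0)
        assert (rep.ppv, rep.npv, rep.auc) == (1.0, 1.0, 1.0)

    def test_constant_probabilities_flag_degenerate_cells(self):
        y = np.array([0, 1] * 10)
        rep = classification_metrics(np.full(20, 0.5), y)
        assert rep.warnings  # one side of the table is empty
        assert rep.accuracy == 0.5

    def test_toy_confusion_table_arithmetic(self):
        """TP=30, FN=4, TN=70, FP=8 hand-computed rates."""
        probs = np.concatenate([
            np.full(30, 0.9), np.full(4, 0.1),   # positives
            np.full(70, 0.1), np.full(8, 0.9),   # negatives
        ])
        y = np.concatenate([np.ones(34), np.zeros(78)]).astype(int)
        rep = classification_metrics(probs, y, threshold=0.5)
        assert rep.sensitivity == pytest.approx(30 / 34, abs=5e-4)   # 0.882
        assert rep.specificity == pytest.approx(70 / 78, abs=5e-4)   # 0.897
        assert rep.ppv == pytest.approx(30 / 38, abs=5e-4)           # 0.789
        assert rep.npv == pytest.approx(70 / 74, abs=5e-4)           # 0.946
        assert rep.accuracy == pytest.approx(100 / 112, abs=5e-4)    # 0.893

    def test_accuracy_consistency_invariant(self, rng):
        probs = rng.random(200)
        y = rng.integers(0, 2, 200)
        rep = classification_metrics(probs, y)
        prev = y.mean()
        assert rep.accuracy == pytest.approx(
            rep.sensitivity * prev + rep.specificity * (1 - prev)
        )

    def test_youden_threshold_maximizes_j(self, rng):
        probs = rng.random(100)
        y = (rng.random(100) < probs).astype(int)
        t = youden_threshold(probs, y)
        rep = classification_metrics(probs, y, threshold=t)
        j_best = rep.sensitivity + rep.specificity - 1
        for tt in np.linspace(0.05, 0.95, 19):
            r = classification_metrics(probs, y, threshold=tt)
            assert j_best >= r.sensitivity + r.specificity - 1 - 1e-9


class TestCalibration:
    def test_well_calibrated_probabilities_recover_identity(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.05, 0.95, 5000)
        y = (rng.random(5000) < p).astype(int)
        points, intercept, slope = calibration_curve(p, y)
        assert slope == pytest.approx(1.0, abs=0.1)
        assert intercept == pytest.approx(0.0, abs=0.15)
        assert np.allclose(points["observed"], points["mean_predicted"], atol=0.07)

    def test_anticalibrated_pattern_detected(self):
        y = np.array([0, 1] * 50)
        p = 0.5 + 0.5 * (y - 0.5)  # deterministic 0.25/0.75
        points, intercept, slope = calibration_curve(p, y, n_bins=2)
        assert slope > 2.0  # overconfident mapping flagged by steep slope

    def test_identical_probs_merge_to_single_bin(self):
        y = np.array([0, 1, 0, 1, 1, 0, 0, 1, 1, 0])
        points, intercept, slope = calibration_curve(np.full(10, 0.4), y)
        assert len(points) == 1
        assert np.isnan(slope)


class TestDecisionCurve:
    def test_treat_all_limit_is_prevalence(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        dca = decision_curve(np.linspace(0, 1, 10), y, thresholds=[0.001])
        assert dca["nb_all"].iloc[0] == pytest.approx(0.3, abs=0.01)

    def test_perfect_model_net_benefit_equals_prevalence(self):
        y = np.array([1, 0, 1, 0, 0, 0, 1, 0])
        probs = y.astype(float) * 0.9 + 0.05
        dca = decision_curve(probs, y, thresholds=np.arange(0.1, 0.9, 0.1))
        assert np.allclose(dca["nb_model"], y.mean())

    def test_toy_hand_computed_net_benefit(self):
        """n=10, 3 events; at pt=0.2: TP=2, FP=2 ->
        NB = 2/10 - (2/10)(0.2/0.8) = 0.15."""
        probs = np.array([0.9, 0.6, 0.1, 0.7, 0.3, 0.15, 0.05, 0.1, 0.12, 0.18])
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        dca = decision_curve(probs, y, thresholds=[0.2])
        assert dca["nb_model"].iloc[0] == pytest.approx(0.2 - 0.2 * 0.25)
        assert dca["nb_all"].iloc[0] == pytest.approx(0.3 - 0.7 * 0.25)
        assert dca["nb_none"].iloc[0] == 0.0

    def test_net_benefit_bounded_by_prevalence(self, rng):
        probs = rng.random(200)
        y = rng.integers(0, 2, 200)
        dca = decision_curve(probs, y)
        assert (dca["nb_model"] <= y.mean() + 1e-12).all()

    def test_unit_threshold_excluded(self):
        dca = decision_curve([0.5, 0.6], [0, 1], thresholds=[0.5, 1.0])
        assert list(dca["threshold"]) == [0.5]
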