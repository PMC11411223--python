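"""Classifier setups: probability combination, cutoffs, determinism, tuning."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import fbeta_score

from sepsistraj import (ModelSpec, TrajectoryClassifier, select_cutoff_f05,
                        tune_hyperparams)
from sepsistraj.errors import (ConfigurationError, ContractViolation,
                               TrainingError, UndefinedMetricError)
from sepsistraj.models import fit


def _toy_data(n=240, seed=0, priors=(0.2, 0.4, 0.4)):
    rng = np.random.default_rng(seed)
    y = rng.choice(3, size=n, p=priors)
    centers = np.array([[2.0, 0.0], [0.0, 2.0], [-2.0, -1.0]])
    X = centers[y] + rng.normal(0, 1.2, size=(n, 2))
    return pd.DataFrame(X, columns=["f1", "f2"]), y


class TestSelectCutoffF05:
    def test_separable_example(self):
        t = select_cutoff_f05([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1])
        assert t == 0.6

    def test_perfect_separation_reaches_f05_of_one(self):
        s = np.r_[np.linspace(0, 0.4, 10), np.linspace(0.6, 1, 10)]
        y = np.r_[np.zeros(10), np.ones(10)]
        t = select_cutoff_f05(s, y)
        pred = s >= t
        assert fbeta_score(y, pred, beta=0.5) == 1.0

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            select_cutoff_f05([0.2, 0.8], [1, 1])

    def test_matches_sklearn_brute_force(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 40))
            s = rng.random(n)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            got = select_cutoff_f05(s, y)
            grid = np.unique(s)
            f = np.array([fbeta_score(y, s >= t, beta=0.5, zero_division=0)
                          for t in grid])
            best = grid[f >= f.max() - 1e-12].max()
            assert got == pytest.approx(best)


class TestSetups:
    @pytest.mark.parametrize("arch", ["gbm", "rf", "lr"])
    @pytest.mark.parametrize("setup", ["two_way", "nested", "multiclass"])
    def test_probability_triples_normalised(self, arch, setup):
        X, y = _toy_data()
        res = TrajectoryClassifier(X, y, architecture=arch, setup=setup).fit()
        P = res.predict_proba3(X)
        assert P.shape == (len(X), 3)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert (P >= 0).all() and (P <= 1).all()

    def test_nested_chain_rule_exact(self):
        X, y = _toy_data()
        res = TrajectoryClassifier(X, y, architecture="lr",
                                   setup="nested").fit()
        Xp = res._prepare(X)
        pa = res.learners["rapid_vs_rest"].predict_proba(Xp)[:, 1]
        pb = res.learners["persistent_vs_recovery"].predict_proba(Xp)[:, 1]
        P = res.predict_proba3(X)
        np.testing.assert_allclose(P[:, 0], pa, atol=1e-12)
        np.testing.assert_allclose(P[:, 1], (1 - pa) * pb, atol=1e-12)
        np.testing.assert_allclose(P[:, 2], (1 - pa) * (1 - pb), atol=1e-12)

    def test_two_way_splits_rest_by_prevalence(self):
        X, y = _toy_data(priors=(0.1, 0.4, 0.5))
        res = TrajectoryClassifier(X, y, architecture="lr",
                                   setup="two_way").fit()
        P = res.predict_proba3(X)
        counts = np.bincount(y, minlength=3)
        ratio = counts[0] / counts[2]
        np.testing.assert_allclose(P[:, 0] / P[:, 2], ratio, rtol=1e-9)

    def test_same_seed_identical_predictions(self):
        X, y = _toy_data()
        spec = ModelSpec(architecture="gbm", setup="multiclass", seed=7)
        p1 = fit(spec, X, y).predict_proba3(X)
        p2 = fit(spec, X, y).predict_proba3(X)
        np.testing.assert_array_equal(p1, p2)

    def test_missing_class_raises_training_error(self):
        X, y = _toy_data()
        keep = y != 0
        with pytest.raises(TrainingError, match="0"):
            TrajectoryClassifier(X[keep], y[keep], setup="nested").fit()
        with pytest.raises(TrainingError):
            TrajectoryClassifier(X[keep], y[keep], setup="multiclass").fit()

    def test_predict_with_missing_columns_raises(self):
        X, y = _toy_data()
        res = TrajectoryClassifier(X, y, setup="multiclass").fit()
        with pytest.raises(ContractViolation, match="f2"):
            res.predict_proba3(X[["f1"]])

    def test_summary_mentions_spec(self):
        X, y = _toy_data()
        res = TrajectoryClassifier(X, y, architecture="rf").fit()
        s = res.summary()
        assert "rf" in s and "multiclass" in s


class TestPointPredict:
    def test_argmax_and_tie_break(self):
        X, y = _toy_data()
        res = TrajectoryClassifier(X, y, setup="multiclass").fit()
        assert np.argmax(np.array([0.2, 0.5, 0.3])) == 1
        # tie-break convention is the lower label index
        assert np.argmax(np.array([0.4, 0.4, 0.2])) == 0
        labels = res.point_predict(X)
        P = res.predict_proba3(X)
        np.testing.assert_array_equal(labels, P.argmax(axis=1))

    def test_two_way_threshold_rule(self):
        X, y = _toy_data()
        res = TrajectoryClassifier(X, y, architecture="lr",
                                   setup="two_way").fit()
        P = res.predict_proba3(X)
        labels = res.point_predict(X)
        assert ((labels == 1) == (P[:, 1] >= res.cutoffs[1])).all()

    def test_nested_cutoff_rule_yields_all_classes(self):
        X, y = _toy_data()
        res = TrajectoryClassifier(X, y, architecture="lr",
                                   setup="nested").fit()
        labels = res.point_predict(X)
        assert set(labels) == {0, 1, 2}


class TestTuneHyperparams:
    def _split(self):
        X, y = _toy_data(n=300, seed=4)
        return (X.iloc[:200], y[:200]), (X.iloc[200:], y[200:])

    def test_budget_one_returns_a_candidate(self):
        train, cal = self._split()
        hp = tune_hyperparams(ModelSpec(architecture="lr"), train, cal,
                              budget=1, seed=0, method="random")
        assert "C" in hp

    def test_invalid_budget(self):
        train, cal = self._split()
        with pytest.raises(ConfigurationError):
            tune_hyperparams(ModelSpec(), train, cal, budget=0)

    def test_deterministic_under_seed(self):
        train, cal = self._split()
        a = tune_hyperparams(ModelSpec(architecture="lr"), train, cal,
                             budget=4, seed=5, method="gp")
        b = tune_hyperparams(ModelSpec(architecture="lr"), train, cal,
                             budget=4, seed=5, method="gp")
        assert a == b

    def test_overlapping_sets_rejected(self):
        X, y = _toy_data(n=100)
        with pytest.raises(ContractViolation):
            tune_hyperparams(ModelSpec(), (X, y), (X.iloc[:10], y[:10]),
                             budget=1)

    def test_search_does_no_harm(self):
        from sepsistraj.metrics import auroc
        train, cal = self._split()
        spec = ModelSpec(architecture="lr")
        hp = tune_hyperparams(spec, train, cal, budget=8, seed=1,
                              method="random")
        base = fit(spec, *train).predict_proba3(cal[0])[:, 1]
        tuned = fit(ModelSpec(architecture="lr", hyperparams=hp),
                    *train).predict_proba3(cal[0])[:, 1]
        yb = (cal[1] == 1).astype(int)
        assert auroc(tuned, yb) >= auroc(base, yb) - 0.01


def test_planted_signal_recovery(modelling_data):
    """Multiclass GBM separates the planted trajectory classes strongly."""
    from sepsistraj.metrics import auroc
    matrix, y = modelling_data
    n = len(y)
    tr, te = np.arange(n) % 3 != 0, np.arange(n) % 3 == 0
    res = TrajectoryClassifier(matrix.X.iloc[tr], y[tr],
                               spec=ModelSpec(seed=0)).fit()
    P = res.predict_proba3(matrix.X.iloc[te])
    for c in range(3):
        yb = (y[te] == c).astype(int)
        assert auroc(P[:, c], yb) > 0.9
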