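"""Mondrian conformal machinery: p-values, regions, tallies, guarantees."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from sepsistraj import (MondrianConformal, SignificanceVector,
                        TrajectoryClassifier, efficiency_validity,
                        predict_region, tally_regions)
from sepsistraj.conformal import (CalibrationStore, calibrate,
                                  multiple_breakdown, nonconformity, pvalue,
                                  pvalue_matrix, regions_from_pvalues)
from sepsistraj.errors import ContractViolation, DataError
from sepsistraj.models import ModelSpec


class TestNonconformity:
    def test_one_minus_probability(self):
        assert nonconformity((0.2, 0.5, 0.3), 1) == pytest.approx(0.5)
        assert nonconformity((0.0, 1.0, 0.0), 1) == 0.0
        assert nonconformity((1.0, 0.0, 0.0), 1) == 1.0

    def test_invalid_class(self):
        with pytest.raises(ContractViolation):
            nonconformity((0.2, 0.5, 0.3), 3)


class TestPValue:
    def _store(self, scores):
        return CalibrationStore({0: np.sort(scores), 1: np.sort(scores),
                                 2: np.sort(scores)})

    def test_counting_example(self):
        store = self._store([0.1, 0.2, 0.3])
        assert pvalue(store, 0, 0.25) == pytest.approx(0.5)  # (1+1)/4

    def test_extreme_score_gets_smallest_pvalue(self):
        store = self._store([0.1, 0.2, 0.3])
        assert pvalue(store, 0, 0.99) == pytest.approx(1 / 4)

    def test_zero_score_gets_pvalue_one(self):
        store = self._store([0.1, 0.2, 0.3])
        assert pvalue(store, 0, 0.0) == 1.0

    def test_tie_counts_as_greater_or_equal(self):
        store = self._store([0.1, 0.2, 0.3])
        assert pvalue(store, 0, 0.2) == pytest.approx((2 + 1) / 4)

    def test_matrix_agrees_with_scalar(self, rng):
        store = self._store(rng.random(50))
        triples = rng.dirichlet([1, 1, 1], size=200)
        P = pvalue_matrix(store, triples)
        for i in [0, 17, 199]:
            for c in range(3):
                assert P[i, c] == pytest.approx(
                    pvalue(store, c, 1 - triples[i, c]))


class TestCalibrate:
    def _fitted(self):
        rng = np.random.default_rng(3)
        y = rng.choice(3, 200, p=[0.2, 0.4, 0.4])
        X = pd.DataFrame(
            np.eye(3)[y] * 2 + rng.normal(0, 1, (200, 3)),
            columns=list("abc"))
        res = TrajectoryClassifier(
            X, y, spec=ModelSpec(architecture="lr")).fit()
        return res, X, y

    def test_one_score_per_patient_conserved(self):
        res, X, y = self._fitted()
        store = calibrate(res, X, y)
        assert sum(len(s) for s in store.scores_by_class.values()) == len(y)
        for c in range(3):
            assert store.n_by_class[c] == int((y == c).sum())

    def test_deterministic(self):
        res, X, y = self._fitted()
        s1 = calibrate(res, X, y)
        s2 = calibrate(res, X, y)
        for c in range(3):
            np.testing.assert_array_equal(s1.scores_by_class[c],
                                          s2.scores_by_class[c])

    def test_absent_class_raises(self):
        res, X, y = self._fitted()
        keep = y != 0
        with pytest.raises(DataError, match="0"):
            calibrate(res, X[keep], y[keep])

    def test_two_way_rejected_for_conformal(self):
        rng = np.random.default_rng(0)
        y = rng.choice(3, 120)
        X = pd.DataFrame(rng.normal(size=(120, 2)), columns=["a", "b"])
        res = TrajectoryClassifier(
            X, y, spec=ModelSpec(architecture="lr", setup="two_way")).fit()
        with pytest.raises(ContractViolation):
            MondrianConformal(res)


class TestRegions:
    def test_membership_rule(self):
        P = np.array([[0.02, 0.30, 0.40]])
        member = regions_from_pvalues(P, 0.25)
        assert member.tolist() == [[False, True, True]]

    def test_eps_zero_gives_full_region(self, rng):
        P = pvalue_matrix(CalibrationStore(
            {c: np.sort(rng.random(20)) for c in range(3)}),
            rng.dirichlet([1, 1, 1], 50))
        member = regions_from_pvalues(P, 0.0)
        assert member.all()

    def test_eps_one_gives_empty_region(self, rng):
        P = rng.random((50, 3))
        assert not regions_from_pvalues(P, 1.0).any()

    def test_regions_shrink_monotonically_in_eps(self, rng):
        P = rng.random((200, 3))
        prev = None
        for e in np.linspace(0, 1, 21):
            member = regions_from_pvalues(P, float(e))
            if prev is not None:
                assert (member <= prev).all()  # never grows
            prev = member

    def test_predict_region_object(self):
        store = CalibrationStore({c: np.sort(np.linspace(0, 1, 19))
                                  for c in range(3)})
        region = predict_region(store, (0.7, 0.2, 0.1), 0.25, "P1")
        assert region.patient_id == "P1"
        assert 0 in region.region
        assert region.category in ("single", "multiple")
        assert region.region == frozenset(
            c for c in range(3) if region.pvalues[c] > 0.25)


class TestTally:
    def test_category_rules(self):
        member = np.array([
            [False, True, True],   # truth 1 -> multiple
            [False, False, True],  # truth 1 -> error
            [False, True, False],  # truth 1 -> single
            [False, False, False],  # truth 1 -> empty
        ])
        t = tally_regions(member, [1, 1, 1, 1])
        row = t[t["true_class"] == 1].iloc[0]
        assert (row["multiple"], row["error"], row["single"],
                row["empty"]) == (1, 1, 1, 1)
        assert row["error_rate"] == pytest.approx(0.5)

    def test_categories_partition_each_class(self, rng):
        member = rng.random((300, 3)) > 0.4
        y = rng.integers(0, 3, 300)
        t = tally_regions(member, y)
        for _, row in t.iterrows():
            assert (row["empty"] + row["error"] + row["single"]
                    + row["multiple"]) == row["n"]

    def test_multiple_breakdown_totals(self, rng):
        member = rng.random((300, 3)) > 0.4
        y = rng.integers(0, 3, 300)
        t = tally_regions(member, y)
        bd = multiple_breakdown(member, y)
        n_multi_regions = int((member.sum(axis=1) >= 2).sum())
        assert bd["total"].sum() == n_multi_regions
        covered_multi = t[t["true_class"] == "overall"]["multiple"].iloc[0]
        diag = sum(bd.loc[i, f"true_{c}"]
                   for i, combo in enumerate([(0, 1), (0, 2), (1, 2),
                                              (0, 1, 2)])
                   for c in combo)
        assert diag == covered_multi


class TestMixedConfidence:
    def test_mixed_vector_tally_partitions(self, rng):
        P = rng.random((400, 3))
        y = rng.integers(0, 3, 400)
        eps = SignificanceVector.of({0: 0.25, 1: 0.25, 2: 0.15})
        member = regions_from_pvalues(P, eps)
        t = tally_regions(member, y)
        assert (t["empty"] + t["error"] + t["single"] + t["multiple"]
                == t["n"]).all()

    def test_efficiency_validity_report(self, rng):
        P = rng.random((200, 3))
        y = rng.integers(0, 3, 200)
        rep = efficiency_validity(P, y, 0.2,
                                  grid=np.array([0.0, 0.2, 1.0]))
        assert 0 <= rep["efficiency"] <= 1
        curve = rep["error_curve"]
        at_zero = curve[(curve["significance"] == 0.0)
                        & (curve["true_class"] == "overall")]
        assert at_zero["error_rate"].iloc[0] == 0.0
        at_one = curve[(curve["significance"] == 1.0)
                       & (curve["true_class"] == "overall")]
        assert at_one["error_rate"].iloc[0] == 1.0
        dist = rep["label_distribution_curve"]
        s = dist.groupby("significance")["fraction"].sum()
        # single+multiple+empty fractions account for every patient
        assert ((s - (1 - s.index * 0)) <= 1.0 + 1e-9).all()


def test_smoothed_pvalues_uniform_under_exchangeability(rng):
    """Scores drawn from one distribution for calibration and test: smoothed
    Mondrian p-values must be Uniform(0,1)."""
    cal_scores = {c: np.sort(rng.normal(size=300)) for c in range(3)}
    store = CalibrationStore(cal_scores)
    y = rng.integers(0, 3, 3000)
    test_scores = rng.normal(size=3000)
    # feed scores through the 1 - p parameterisation used by the matrix API
    triples = np.full((3000, 3), 0.5)
    triples[np.arange(3000), y] = 1 - test_scores
    P = pvalue_matrix(store, triples, smoothed=True,
                      rng=np.random.default_rng(7))
    pv = P[np.arange(3000), y]
    assert kstest(pv, "uniform").pvalue > 0.01


def test_unsmoothed_pvalues_super_uniform(rng):
    store = CalibrationStore({c: np.sort(rng.random(100)) for c in range(3)})
    y = rng.integers(0, 3, 2000)
    triples = np.full((2000, 3), 0.5)
    triples[np.arange(2000), y] = 1 - rng.random(2000)
    P = pvalue_matrix(store, triples)
    pv = P[np.arange(2000), y]
    for e in (0.1, 0.25, 0.5):
        assert (pv <= e).mean() <= e + 3 * np.sqrt(e * (1 - e) / 2000) + 0.02
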