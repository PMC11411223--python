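"""Mondrian (class-conditional) conformal prediction over trajectory triples.

A calibration set, disjoint from training, contributes one nonconformity
score per patient — ``1 − p_true-class`` under the fitted classifier — to
the score list of its *true* class only.  For a test patient and candidate
class ``c`` the conformal p-value is

    p_c = (#{calibration scores of class c ≥ test score} + 1) / (n_c + 1)

and the prediction region at a per-class significance vector ε is
``{c : p_c > ε_c}``.  Working per class makes the coverage guarantee hold
within each class (the Mondrian property), which matters for unbalanced
trajectory data: rare rapid-death patients get their own error budget.
Regions may be empty, a single label, or multiple labels; multiple-label
regions are exactly the predictions a trial screening workflow defers to a
human reviewer.

Unsmoothed (conservative) p-values are the default; the smoothed variant
breaks ties with a seeded uniform draw and makes the p-values exactly
uniform under exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractViolation, DataError

__all__ = ["CalibrationStore", "SignificanceVector", "PredictionRegion",
           "nonconformity", "calibrate", "pvalue", "pvalue_matrix",
           "regions_from_pvalues", "predict_region", "tally_regions",
           "multiple_breakdown", "efficiency_validity", "MondrianConformal",
           "ConformalResults", "DEFAULT_MIXED_EPS"]

CLASSES = (0, 1, 2)

#: Mixed-confidence default: 85% confidence for recovery, 75% for rapid
#: death and persistent ill.
DEFAULT_MIXED_EPS = {0: 0.25, 1: 0.25, 2: 0.15}


@dataclass(frozen=True)
class SignificanceVector:
    """Per-class significance (1 − confidence); a scalar applies to all."""

    eps: dict[int, float]

    @classmethod
    def of(cls, value) -> "SignificanceVector":
        if isinstance(value, SignificanceVector):
            return value
        if np.isscalar(value):
            return cls({c: float(value) for c in CLASSES})
        return cls({int(c): float(e) for c, e in dict(value).items()})

    def __post_init__(self):
        for c in CLASSES:
            if c not in self.eps:
                raise ContractViolation(f"significance missing class {c}")
            if not 0.0 <= self.eps[c] <= 1.0:
                raise ContractViolation("significance must be in [0, 1]")

    def __getitem__(self, c: int) -> float:
        return self.eps[c]


@dataclass
class CalibrationStore:
    """Sorted per-class nonconformity scores from the calibration set."""

    scores_by_class: dict[int, np.ndarray]

    @property
    def n_by_class(self) -> dict[int, int]:
        return {c: len(s) for c, s in self.scores_by_class.items()}


@dataclass(frozen=True)
class PredictionRegion:
    patient_id: str
    pvalues: dict[int, float]
    region: frozenset[int]

    @property
    def category(self) -> str:
        k = len(self.region)
        return "empty" if k == 0 else ("single" if k == 1 else "multiple")


def nonconformity(prob_triple, cls: int) -> float:
    """Inverse-probability score, 1 − p_class (higher = more nonconforming)."""
    if cls not in CLASSES:
        raise ContractViolation(f"class must be one of {CLASSES}, got {cls}")
    p = np.asarray(prob_triple, dtype=float)
    return float(1.0 - p[cls])


def calibrate(results, features_cal, labels_cal) -> CalibrationStore:
    """Score the calibration patients under the fitted model, per true class."""
    y = np.asarray(labels_cal).astype(int)
    proba = results.predict_proba3(features_cal)
    scores = 1.0 - proba[np.arange(len(y)), y]
    store: dict[int, np.ndarray] = {}
    for c in CLASSES:
        sc = np.sort(scores[y == c])
        if sc.size == 0:
            raise DataError(
                f"class {c} absent from the calibration set; its error rate "
                "cannot be guaranteed")
        store[c] = sc
    return CalibrationStore(store)


def pvalue(store: CalibrationStore, cls: int, test_score: float) -> float:
    """Unsmoothed conformal p-value for one class/score."""
    s = store.scores_by_class.get(cls)
    if s is None or len(s) == 0:
        raise DataError(f"no calibration scores for class {cls}")
    n_ge = len(s) - np.searchsorted(s, test_score, side="left")
    return float((n_ge + 1) / (len(s) + 1))


def pvalue_matrix(store: CalibrationStore, prob_triples,
                  smoothed: bool = False,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """(n, 3) conformal p-values for every patient × candidate class.

    With ``smoothed=True``, ties between the test score and calibration
    scores are broken by a uniform draw (seeded via ``rng``), giving exactly
    uniform p-values for exchangeable true-class test points.
    """
    P = np.asarray(prob_triples, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ContractViolation("prob_triples must be (n, 3)")
    if smoothed and rng is None:
        rng = np.random.default_rng(0)
    out = np.empty_like(P)
    for c in CLASSES:
        s = store.scores_by_class[c]
        n = len(s)
        test = 1.0 - P[:, c]
        n_gt = n - np.searchsorted(s, test, side="right")
        n_eq = np.searchsorted(s, test, side="right") - \
            np.searchsorted(s, test, side="left")
        if smoothed:
            tau = rng.random(len(test))
            out[:, c] = (n_gt + tau * (n_eq + 1)) / (n + 1)
        else:
            out[:, c] = (n_gt + n_eq + 1) / (n + 1)
    return out


def regions_from_pvalues(P: np.ndarray, eps) -> np.ndarray:
    """Boolean (n, 3) membership matrix: include c iff p_c > ε_c."""
    eps = SignificanceVector.of(eps)
    thr = np.array([eps[c] for c in CLASSES])
    return np.asarray(P) > thr[None, :]


def predict_region(store: CalibrationStore, prob_triple, eps,
                   patient_id: str = "") -> PredictionRegion:
    """Single-patient convenience wrapper around the matrix path."""
    P = pvalue_matrix(store, np.asarray(prob_triple, dtype=float)[None, :])
    member = regions_from_pvalues(P, eps)[0]
    return PredictionRegion(
        patient_id=patient_id,
        pvalues={c: float(P[0, c]) for c in CLASSES},
        region=frozenset(int(c) for c in CLASSES if member[c]))


def tally_regions(member: np.ndarray, truth) -> pd.DataFrame:
    """Per-true-class and overall counts of empty/error/single/multiple.

    ``empty``: no label in the region; ``error``: non-empty region missing
    the true label; ``single``: region is exactly the true label;
    ``multiple``: ≥2 labels including the true one.  The four categories
    partition each class.  ``error_rate`` = (empty + error) / n is the
    quantity the per-class validity guarantee bounds.
    """
    member = np.asarray(member, dtype=bool)
    y = np.asarray(truth).astype(int)
    size = member.sum(axis=1)
    covered = member[np.arange(len(y)), y]
    cat = np.where(size == 0, "empty",
                   np.where(~covered, "error",
                            np.where(size == 1, "single", "multiple")))
    rows = []
    for c in list(CLASSES) + ["overall"]:
        m = np.ones(len(y), bool) if c == "overall" else (y == c)
        n = int(m.sum())
        counts = {k: int((cat[m] == k).sum())
                  for k in ("empty", "error", "single", "multiple")}
        rows.append({"true_class": c, "n": n, **counts,
                     "error_rate": ((counts["empty"] + counts["error"]) / n
                                    if n else np.nan)})
    return pd.DataFrame(rows)


def multiple_breakdown(member: np.ndarray, truth) -> pd.DataFrame:
    """Composition of multiple-label regions ({0,1}, {0,2}, {1,2}, {0,1,2})
    cross-tabulated against the true class."""
    member = np.asarray(member, dtype=bool)
    y = np.asarray(truth).astype(int)
    combos = [(0, 1), (0, 2), (1, 2), (0, 1, 2)]
    rows = []
    for combo in combos:
        mask = member.sum(axis=1) == len(combo)
        for c in combo:
            mask &= member[:, c]
        row = {"region": "{" + ",".join(map(str, combo)) + "}"}
        for c in CLASSES:
            row[f"true_{c}"] = int((mask & (y == c)).sum())
        row["total"] = int(mask.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def efficiency_validity(P: np.ndarray, truth, eps,
                        grid: np.ndarray | None = None) -> dict:
    """Efficiency, per-class validity, and significance-sweep curves.

    Returns a dict with ``efficiency`` (fraction of single correct
    predictions at ε), ``tally`` (the category table at ε), and two
    long-format curve tables over ``grid`` (default 0.0–1.0 by 0.05): the
    observed per-class error rate versus significance, and the
    single/multiple/empty label-distribution versus significance.
    """
    P = np.asarray(P, dtype=float)
    y = np.asarray(truth).astype(int)
    eps = SignificanceVector.of(eps)
    member = regions_from_pvalues(P, eps)
    tally = tally_regions(member, y)
    n = len(y)
    efficiency = float(tally.loc[tally["true_class"] == "overall",
                                 "single"].iloc[0]) / n if n else np.nan

    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 3)
    err_rows, dist_rows = [], []
    for e in grid:
        mem = P > float(e)
        t = tally_regions(mem, y)
        for _, r in t.iterrows():
            err_rows.append({"significance": float(e),
                             "true_class": r["true_class"],
                             "error_rate": r["error_rate"]})
        ov = t[t["true_class"] == "overall"].iloc[0]
        for k in ("single", "multiple", "empty"):
            dist_rows.append({"significance": float(e), "category": k,
                              "fraction": ov[k] / n if n else np.nan})
    return {
        "efficiency": efficiency,
        "tally": tally,
        "validity": {
            c: {"error_rate": float(
                tally.loc[tally["true_class"] == c, "error_rate"].iloc[0]),
                "eps": eps[c]}
            for c in CLASSES},
        "error_curve": pd.DataFrame(err_rows),
        "label_distribution_curve": pd.DataFrame(dist_rows),
    }


class MondrianConformal:
    """Conformal wrapper around fitted trajectory results.

    ``MondrianConformal(results).calibrate(X_cal, y_cal)`` returns a
    :class:`ConformalResults` whose ``predict`` emits per-patient p-values,
    regions and categories at any significance vector.
    """

    def __init__(self, results):
        if results.spec.setup == "two_way":
            raise ContractViolation(
                "conformal prediction requires genuine 3-class probability "
                "triples (multiclass or nested setup)")
        self.results = results

    def calibrate(self, features_cal, labels_cal) -> "ConformalResults":
        store = calibrate(self.results, features_cal, labels_cal)
        return ConformalResults(self.results, store,
                                n_calibration=len(np.asarray(labels_cal)))


@dataclass
class ConformalResults:
    results: object
    store: CalibrationStore
    n_calibration: int

    def pvalues(self, features, smoothed: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        proba = self.results.predict_proba3(features)
        return pvalue_matrix(self.store, proba, smoothed=smoothed, rng=rng)

    def predict(self, features, eps=DEFAULT_MIXED_EPS,
                smoothed: bool = False,
                rng: np.random.Generator | None = None) -> pd.DataFrame:
        X = features.X if hasattr(features, "X") else features
        P = self.pvalues(X, smoothed=smoothed, rng=rng)
        member = regions_from_pvalues(P, eps)
        size = member.sum(axis=1)
        region_str = ["{" + ",".join(str(c) for c in CLASSES if row[c]) + "}"
                      for row in member]
        cat = np.where(size == 0, "empty",
                       np.where(size == 1, "single", "multiple"))
        idx = X.index if hasattr(X, "index") else pd.RangeIndex(len(P))
        return pd.DataFrame({
            "p0": P[:, 0], "p1": P[:, 1], "p2": P[:, 2],
            "region": region_str, "category": cat,
        }, index=idx)
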