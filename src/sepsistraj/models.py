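"""Three-class trajectory classifiers in three setups.

Architectures: gradient boosting (LightGBM), random forest, logistic
regression.  Setups:

* ``two_way`` — persistent ill (label 1) versus the rest {0, 2}.  The binary
  probability is spread over labels 0/2 proportionally to their training
  prevalence purely as a derived convenience; two-way triples are not used
  for conformal prediction.
* ``nested`` — stage A predicts rapid death (0) versus {1, 2}; stage B,
  trained on non-rapid-death rows, separates persistent ill (1) from
  recovery (2).  Per-class probabilities combine by the chain rule:
  ``p0 = P_A(0)``, ``p1 = (1 − P_A(0))·P_B(1)``, ``p2 = (1 − P_A(0))·P_B(2)``.
* ``multiclass`` — one native 3-class learner.

Point predictions use the class of highest probability for the multiclass
setup (ties break to the lower label, i.e. conservatively toward rapid
death) and F-0.5-maximising cutoffs for the binary stages of the other two
setups.  Mean imputation is part of the fitted model for architectures that
cannot consume missing values (GBM can).

The modelling surface follows the model/results idiom: build a
:class:`TrajectoryClassifier` from data, call :meth:`~TrajectoryClassifier.fit`,
and work with the returned :class:`TrajectoryResults`.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import (ConfigurationError, ContractViolation, TrainingError,
                     UndefinedMetricError)
from .features import FeatureMatrix, MeanImputer

__all__ = ["ModelSpec", "TrajectoryClassifier", "TrajectoryResults",
           "fit", "predict_proba3", "point_predict", "select_cutoff_f05",
           "tune_hyperparams", "ARCHITECTURES", "SETUPS"]

ARCHITECTURES = ("gbm", "rf", "lr")
SETUPS = ("two_way", "nested", "multiclass")


@dataclass(frozen=True)
class ModelSpec:
    architecture: str = "gbm"
    setup: str = "multiclass"
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0
    needs_imputation: bool | None = None  # default: every arch but gbm

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if self.setup not in SETUPS:
            raise ConfigurationError(f"unknown setup {self.setup!r}")

    @property
    def imputes(self) -> bool:
        if self.needs_imputation is None:
            return self.architecture != "gbm"
        return self.needs_imputation


_GBM_DEFAULTS = dict(n_estimators=300, learning_rate=0.05, num_leaves=31,
                     min_child_samples=20, subsample=1.0, colsample_bytree=0.9)
_RF_DEFAULTS = dict(n_estimators=300, min_samples_leaf=2, max_features="sqrt")
_LR_DEFAULTS = dict(C=1.0, max_iter=2000)


def _make_learner(spec: ModelSpec):
    hp = dict(spec.hyperparams)
    if spec.architecture == "gbm":
        import lightgbm as lgb
        params = {**_GBM_DEFAULTS, **hp}
        return lgb.LGBMClassifier(random_state=spec.seed, n_jobs=1,
                                  deterministic=True, force_row_wise=True,
                                  verbosity=-1, **params)
    if spec.architecture == "rf":
        params = {**_RF_DEFAULTS, **hp}
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1,
                                      **params)
    params = {**_LR_DEFAULTS, **hp}
    return make_pipeline(StandardScaler(),
                         LogisticRegression(random_state=spec.seed, **params))


def _as_frame(features) -> pd.DataFrame:
    return features.X if isinstance(features, FeatureMatrix) else features


def select_cutoff_f05(scores, binary_labels) -> float:
    """Threshold over the unique-score grid maximising F-0.5 (ties → higher).

    F_{0.5} = (1 + 0.5²)·PPV·TPR / (0.5²·PPV + TPR); a threshold predicting
    no positives scores 0.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels).astype(int)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("both classes required to select a cutoff")
    grid = np.unique(s)
    best_f, best_t = -1.0, grid[0]
    for t in grid:
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        fn = int((~pred & (y == 1)).sum())
        # integer form of (1+0.5²)·PPV·TPR / (0.5²·PPV + TPR): exact, so
        # mathematically tied thresholds compare equal
        f = 5 * tp / (5 * tp + fn + 4 * fp) if tp else 0.0
        if f >= best_f:  # >= walks ties toward the higher threshold
            best_f, best_t = f, float(t)
    return best_t


def _binary_pos_proba(learner, X) -> np.ndarray:
    proba = learner.predict_proba(X)
    return proba[:, list(learner.classes_).index(1)]


class TrajectoryClassifier:
    """Model object: data plus a :class:`ModelSpec`; ``fit()`` -> results."""

    def __init__(self, features, labels, spec: ModelSpec | None = None,
                 **spec_kwargs):
        self.spec = spec if spec is not None else ModelSpec(**spec_kwargs)
        self.X = _as_frame(features)
        self.y = np.asarray(labels).astype(int)
        if len(self.X) != len(self.y):
            raise ContractViolation("features and labels length mismatch")
        if not np.isin(self.y, [0, 1, 2]).all():
            raise ContractViolation("labels must be in {0, 1, 2}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "trajectory",
                       spec: ModelSpec | None = None, **spec_kwargs):
        y = df[label_col].to_numpy()
        X = df.drop(columns=[label_col])
        return cls(X, y, spec=spec, **spec_kwargs)

    def fit(self) -> "TrajectoryResults":
        spec, X, y = self.spec, self.X, self.y
        present = set(np.unique(y).tolist())
        if spec.setup in ("nested", "multiclass"):
            missing = {0, 1, 2} - present
            if missing:
                raise TrainingError(
                    f"{spec.setup} setup requires all three classes; missing "
                    f"{sorted(missing)}")
        elif 1 not in present or not (present - {1}):
            raise TrainingError("two_way setup requires class 1 and at "
                                "least one other class")

        imputer = None
        Xt = X
        if spec.imputes:
            imputer = MeanImputer().fit(X)
            Xt = imputer.transform(X)

        learners: dict[str, object] = {}
        cutoffs: dict[int, float] = {}
        if spec.setup == "multiclass":
            lrn = _make_learner(spec)
            lrn.fit(Xt, y)
            learners["multiclass"] = lrn
        elif spec.setup == "two_way":
            lrn = _make_learner(spec)
            yb = (y == 1).astype(int)
            lrn.fit(Xt, yb)
            learners["persistent_vs_rest"] = lrn
            cutoffs[1] = select_cutoff_f05(_binary_pos_proba(lrn, Xt), yb)
        else:  # nested
            a = _make_learner(spec)
            ya = (y == 0).astype(int)
            a.fit(Xt, ya)
            learners["rapid_vs_rest"] = a
            sub = y != 0
            b = _make_learner(spec)
            yb = (y[sub] == 1).astype(int)
            b.fit(Xt[sub], yb)
            learners["persistent_vs_recovery"] = b
            cutoffs[0] = select_cutoff_f05(_binary_pos_proba(a, Xt), ya)
            cutoffs[1] = select_cutoff_f05(_binary_pos_proba(b, Xt[sub]), yb)

        counts = np.bincount(y, minlength=3).astype(float)
        rest = counts[0] + counts[2]
        split02 = (np.array([0.5, 0.5]) if rest == 0
                   else np.array([counts[0], counts[2]]) / rest)
        return TrajectoryResults(
            model=self, spec=spec, learners=learners, imputer=imputer,
            columns=list(X.columns), cutoffs=cutoffs,
            class_counts=counts.astype(int), split02=split02)


@dataclass
class TrajectoryResults:
    """Fitted architecture × setup pair exposing 3-class probability triples."""

    model: TrajectoryClassifier
    spec: ModelSpec
    learners: dict
    imputer: MeanImputer | None
    columns: list[str]
    cutoffs: dict[int, float]
    class_counts: np.ndarray
    split02: np.ndarray

    def _prepare(self, features) -> pd.DataFrame:
        X = _as_frame(features)
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise ContractViolation(
                f"feature columns missing at predict time: {missing[:10]}")
        X = X[self.columns]
        if self.imputer is not None:
            X = self.imputer.transform(X)
        return X

    def predict_proba3(self, features) -> np.ndarray:
        """(n, 3) array of class probabilities; rows sum to 1."""
        X = self._prepare(features)
        if self.spec.setup == "multiclass":
            lrn = self.learners["multiclass"]
            proba = lrn.predict_proba(X)
            classes = list(lrn.classes_)
            out = np.zeros((len(X), 3))
            for j, c in enumerate(classes):
                out[:, int(c)] = proba[:, j]
        elif self.spec.setup == "nested":
            pa = _binary_pos_proba(self.learners["rapid_vs_rest"], X)
            pb = _binary_pos_proba(self.learners["persistent_vs_recovery"], X)
            out = np.column_stack([pa, (1 - pa) * pb, (1 - pa) * (1 - pb)])
        else:
            p1 = _binary_pos_proba(self.learners["persistent_vs_rest"], X)
            out = np.column_stack([(1 - p1) * self.split02[0], p1,
                                   (1 - p1) * self.split02[1]])
        return out / out.sum(axis=1, keepdims=True)

    def point_predict(self, features) -> np.ndarray:
        """Point labels; argmax (ties → lower label) or cutoff rules."""
        X = self._prepare(features)
        if self.spec.setup == "multiclass":
            return np.argmax(self.predict_proba3(X), axis=1)
        if self.spec.setup == "two_way":
            p1 = _binary_pos_proba(self.learners["persistent_vs_rest"], X)
            fallback = 0 if self.split02[0] >= self.split02[1] else 2
            return np.where(p1 >= self.cutoffs[1], 1, fallback)
        pa = _binary_pos_proba(self.learners["rapid_vs_rest"], X)
        pb = _binary_pos_proba(self.learners["persistent_vs_recovery"], X)
        out = np.where(pa >= self.cutoffs[0], 0,
                       np.where(pb >= self.cutoffs[1], 1, 2))
        return out

    def summary(self) -> str:
        lines = [
            "Trajectory classifier results",
            "=" * 46,
            f"architecture: {self.spec.architecture:>12}   setup: {self.spec.setup}",
            f"n = {int(self.class_counts.sum())}  "
            f"(rapid death {self.class_counts[0]}, "
            f"persistent ill {self.class_counts[1]}, "
            f"recovery {self.class_counts[2]})",
            f"features: {len(self.columns)}",
            f"imputation: {'mean (train-fitted)' if self.imputer else 'none'}",
        ]
        if self.cutoffs:
            cut = ", ".join(f"stage {k}: {v:.3f}"
                            for k, v in sorted(self.cutoffs.items()))
            lines.append(f"F-0.5 cutoffs: {cut}")
        return "\n".join(lines)

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        return path

    @staticmethod
    def load(path) -> "TrajectoryResults":
        with open(path, "rb") as fh:
            return pickle.load(fh)


# -- functional aliases matching the pipeline vocabulary -------------------

def fit(spec: ModelSpec, features_train, labels_train) -> TrajectoryResults:
    return TrajectoryClassifier(features_train, labels_train, spec=spec).fit()


def predict_proba3(results: TrajectoryResults, features) -> np.ndarray:
    return results.predict_proba3(features)


def point_predict(results: TrajectoryResults, features) -> np.ndarray:
    return results.point_predict(features)


# -- hyperparameter search -------------------------------------------------

_SPACES = {
    "gbm": {
        "num_leaves": ("int", 8, 64, "log"),
        "learning_rate": ("float", 0.01, 0.3, "log"),
        "n_estimators": ("int", 100, 500, "linear"),
        "min_child_samples": ("int", 5, 50, "linear"),
    },
    "rf": {
        "n_estimators": ("int", 100, 500, "linear"),
        "max_depth": ("int", 3, 24, "linear"),
        "min_samples_leaf": ("int", 1, 10, "linear"),
        "max_features": ("float", 0.2, 1.0, "linear"),
    },
    "lr": {"C": ("float", 1e-3, 100.0, "log")},
}


def _sample_unit(rng, k):
    return rng.random(k)


def _decode(arch: str, u: np.ndarray) -> dict:
    hp = {}
    for (name, (kind, lo, hi, scale)), ui in zip(_SPACES[arch].items(), u):
        if scale == "log":
            val = float(np.exp(np.log(lo) + ui * (np.log(hi) - np.log(lo))))
        else:
            val = float(lo + ui * (hi - lo))
        hp[name] = int(round(val)) if kind == "int" else val
    return hp


def tune_hyperparams(spec: ModelSpec, train, calibration, budget: int,
                     seed: int | None = None, method: str = "gp") -> dict:
    """Seeded hyperparameter search maximising calibration-set AUROC for
    persistent ill (one-vs-rest).

    ``method='gp'`` runs expected-improvement search with a Gaussian-process
    surrogate after a short random warm-up; ``method='random'`` is the plain
    random-search fallback.  Returns the best hyperparameter mapping found
    within ``budget`` evaluations.
    """
    from sklearn.metrics import roc_auc_score

    if budget < 1:
        raise ConfigurationError("tuning budget must be >= 1")
    X_tr, y_tr = train
    X_cal, y_cal = calibration
    X_tr, X_cal = _as_frame(X_tr), _as_frame(X_cal)
    overlap = set(X_tr.index) & set(X_cal.index)
    if overlap:
        raise ContractViolation(
            f"train and calibration sets overlap ({len(overlap)} rows)")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    dim = len(_SPACES[spec.architecture])

    def objective(u: np.ndarray) -> float:
        hp = _decode(spec.architecture, u)
        res = fit(replace(spec, hyperparams=hp), X_tr, y_tr)
        p1 = res.predict_proba3(X_cal)[:, 1]
        return float(roc_auc_score((np.asarray(y_cal) == 1).astype(int), p1))

    evaluated: list[tuple[np.ndarray, float]] = []
    n_warm = min(budget, max(3, dim + 1)) if method == "gp" else budget
    for _ in range(n_warm):
        u = _sample_unit(rng, dim)
        evaluated.append((u, objective(u)))

    if method == "gp":
        from scipy.stats import norm
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import Matern
        while len(evaluated) < budget:
            U = np.array([u for u, _ in evaluated])
            f = np.array([v for _, v in evaluated])
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5), normalize_y=True, alpha=1e-6,
                random_state=int(rng.integers(2**31)))
            gp.fit(U, f)
            cand = rng.random((256, dim))
            mu, sd = gp.predict(cand, return_std=True)
            best = f.max()
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (mu - best) / np.where(sd > 0, sd, 1.0)
                ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
            ei[sd <= 0] = 0.0
            u = cand[int(np.argmax(ei))]
            evaluated.append((u, objective(u)))

    best_u, _ = max(evaluated, key=lambda t: t[1])
    return _decode(spec.architecture, best_u)
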