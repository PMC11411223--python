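"""Additive feature attributions for fitted trajectory models.

Tree models expose exact per-patient Shapley-value attributions through
LightGBM's built-in contribution computation (``pred_contrib``); for each
patient and class the attributions plus the base value reproduce the raw
margin exactly.  Logistic regression uses the closed-form linear
attribution ``coef · (x − x̄)``.  Random forests have no exact fast
attribution path here; requesting one raises a capability error pointing to
the permutation-importance fallback, which works for any fitted model.

Global importance is the mean absolute attribution per feature and class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CapabilityError
from .models import TrajectoryResults

__all__ = ["ExplainResult", "explain", "permutation_importance"]


@dataclass
class ExplainResult:
    """Per-class additive attributions and the derived global ranking."""

    attributions: dict[int, pd.DataFrame]  # class -> (patients × features)
    base_values: dict[int, np.ndarray]
    global_importance: pd.DataFrame  # class, feature, mean_abs_attribution, rank

    def top_features(self, cls: int, k: int = 15) -> list[str]:
        df = self.global_importance
        sub = df[df["class"] == cls].nsmallest(k, "rank")
        return sub["feature"].tolist()

    def top_features_overall(self, k: int = 15) -> list[str]:
        agg = (self.global_importance
               .groupby("feature", sort=False)["mean_abs_attribution"]
               .mean().sort_values(ascending=False))
        return agg.head(k).index.tolist()


def _global_table(attributions: dict[int, pd.DataFrame]) -> pd.DataFrame:
    rows = []
    for c, A in attributions.items():
        imp = A.abs().mean(axis=0)
        order = imp.sort_values(ascending=False)
        ranks = {f: r + 1 for r, f in enumerate(order.index)}
        for f in A.columns:
            rows.append({"class": c, "feature": f,
                         "mean_abs_attribution": float(imp[f]),
                         "rank": ranks[f]})
    return pd.DataFrame(rows)


def explain(results: TrajectoryResults, features, top_k: int = 15
            ) -> ExplainResult:
    """Exact additive attributions for GBM (tree Shapley values) or logistic
    regression; raises :class:`CapabilityError` otherwise."""
    X = results._prepare(features)
    cols = list(X.columns)
    spec = results.spec
    if spec.setup != "multiclass":
        raise CapabilityError(
            "explanations are provided for the multiclass setup; use "
            "permutation_importance for other setups")
    if spec.architecture == "gbm":
        lrn = results.learners["multiclass"]
        contrib = lrn.booster_.predict(X.to_numpy(dtype=float),
                                       pred_contrib=True)
        m = len(cols)
        attributions, bases = {}, {}
        for c in range(3):
            block = contrib[:, c * (m + 1):(c + 1) * (m + 1)]
            attributions[c] = pd.DataFrame(block[:, :m], columns=cols,
                                           index=X.index)
            bases[c] = block[:, m]
    elif spec.architecture == "lr":
        pipe = results.learners["multiclass"]
        scaler, lr = pipe[0], pipe[-1]
        Z = scaler.transform(X)
        attributions, bases = {}, {}
        class_order = list(lr.classes_)
        for c in range(3):
            j = class_order.index(c)
            A = Z * lr.coef_[j][None, :]
            attributions[c] = pd.DataFrame(A, columns=cols, index=X.index)
            bases[c] = np.full(len(X), lr.intercept_[j])
    else:
        raise CapabilityError(
            "no exact additive attribution for random forests here; use "
            "permutation_importance as the fallback")
    return ExplainResult(attributions=attributions, base_values=bases,
                         global_importance=_global_table(attributions))


def permutation_importance(results: TrajectoryResults, features, labels,
                           n_repeats: int = 5, seed: int = 0) -> pd.DataFrame:
    """Model-agnostic global importance: drop in persistent-ill AUROC when a
    column is permuted, averaged over ``n_repeats`` shuffles."""
    from .metrics import auroc

    X = (features.X if hasattr(features, "X") else features).copy()
    y = (np.asarray(labels) == 1).astype(int)
    rng = np.random.default_rng(seed)
    base = auroc(results.predict_proba3(X)[:, 1], y)
    rows = []
    for col in X.columns:
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            drops.append(base - auroc(results.predict_proba3(Xp)[:, 1], y))
        rows.append({"feature": col, "importance": float(np.mean(drops))})
    out = pd.DataFrame(rows).sort_values("importance", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
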