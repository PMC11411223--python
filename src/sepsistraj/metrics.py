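"""Discrimination and calibration metrics.

AUROC is the rank statistic with tie averaging, AUPRC the step-integrated
precision-recall area (both via scikit-learn).  Brier scores are reported
per class in the binary form ``mean (p_c − 1{y=c})²`` with the summed
multiclass form alongside; calibration tables bin predicted probabilities
into deciles with Wilson 95% confidence intervals on the observed rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import UndefinedMetricError

__all__ = ["auroc", "auprc", "wilson_interval", "brier_calibration",
           "tpr_ppv_f05"]


def _check_binary(y):
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError(
            "metric undefined: only one class present")
    return y


def auroc(scores, binary_labels) -> float:
    y = _check_binary(binary_labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(scores, binary_labels) -> float:
    y = _check_binary(binary_labels)
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def wilson_interval(k: int, n: int, alpha: float = 0.05
                    ) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if n == 0:
        return (np.nan, np.nan)
    z = norm.ppf(1 - alpha / 2)
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def tpr_ppv_f05(pred_pos, true_pos) -> tuple[float, float, float]:
    """Sensitivity, positive predictive value and F-0.5 of binary decisions."""
    pred = np.asarray(pred_pos, dtype=bool)
    y = np.asarray(true_pos, dtype=bool)
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    tpr = tp / (tp + fn) if tp + fn else np.nan
    ppv = tp / (tp + fp) if tp + fp else np.nan
    if tp == 0:
        f05 = 0.0
    else:
        f05 = 1.25 * ppv * tpr / (0.25 * ppv + tpr)
    return tpr, ppv, f05


def brier_calibration(prob_triples, labels, n_bins: int = 10
                      ) -> tuple[dict, pd.DataFrame]:
    """Per-class binary Brier scores and a decile calibration table.

    Returns ``(brier, deciles)`` where ``brier`` maps class → binary Brier
    plus ``"multiclass_sum"`` → the summed-squares form, and ``deciles`` is
    a long table (class, bin, n, mean_predicted, observed_rate, ci_low,
    ci_high) with probability-decile bins.
    """
    P = np.asarray(prob_triples, dtype=float)
    y = np.asarray(labels).astype(int)
    onehot = np.eye(3)[y]
    brier = {c: float(np.mean((P[:, c] - onehot[:, c]) ** 2)) for c in range(3)}
    brier["multiclass_sum"] = float(np.mean(((P - onehot) ** 2).sum(axis=1)))

    rows = []
    for c in range(3):
        p = P[:, c]
        obs = onehot[:, c]
        try:
            bins = pd.qcut(p, n_bins, duplicates="drop")
        except ValueError:
            bins = pd.Series(["all"] * len(p))
        df = pd.DataFrame({"p": p, "obs": obs, "bin": bins})
        for b, grp in df.groupby("bin", observed=True):
            k, n = int(grp["obs"].sum()), len(grp)
            lo, hi = wilson_interval(k, n)
            rows.append({"class": c, "bin": str(b), "n": n,
                         "mean_predicted": float(grp["p"].mean()),
                         "observed_rate": k / n, "ci_low": lo, "ci_high": hi})
    return brier, pd.DataFrame(rows)
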