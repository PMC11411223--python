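"""Cross-validation orchestration, feature-subset experiments, and the
end-to-end pipeline.

Repeated stratified k-fold CV (default 10 folds × 50 repeats; reduced
profiles are configured, not hard-coded) refits everything that could leak
— mean imputation, F-0.5 cutoffs, top-k feature selection — inside each
training fold.  Per-fold one-vs-rest AUROC/AUPRC/Brier and cutoff metrics
are aggregated as mean (SD) over all fold evaluations.

``run_pipeline`` chains the seven stages
simulate → cohort → label → featurize → train → conformal-eval → report
and writes every table plus a JSON manifest (config hash, seeds, stage
timings and counts).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

from . import conformal as cp
from .cohort import build_cohort
from .errors import ConfigurationError, DataError
from .features import FeatureMatrix, FeatureRegistry, build_matrix, default_registry
from .io import write_bundles
from .labeling import label_cohort
from .metrics import auprc, auroc, brier_calibration, tpr_ppv_f05
from .models import ModelSpec, TrajectoryClassifier
from .synthetic import SimConfig, generate

__all__ = ["CVPlan", "MetricsReport", "run_cv", "feature_subset_experiment",
           "split_development_set", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVPlan:
    n_folds: int = 10
    n_repeats: int = 50
    seed: int = 0
    stratified: bool = True

    def splitter(self):
        if not self.stratified:
            from sklearn.model_selection import RepeatedKFold
            return RepeatedKFold(n_splits=self.n_folds,
                                 n_repeats=self.n_repeats,
                                 random_state=self.seed)
        return RepeatedStratifiedKFold(n_splits=self.n_folds,
                                       n_repeats=self.n_repeats,
                                       random_state=self.seed)


@dataclass
class MetricsReport:
    """Per-fold metric table with mean (SD) aggregation across evaluations."""

    per_fold: pd.DataFrame  # repeat, fold, class, metric columns
    n_folds_skipped: int = 0
    brier_form: str = "per-class binary"

    def aggregate(self) -> pd.DataFrame:
        metrics = [c for c in self.per_fold.columns
                   if c not in ("repeat", "fold", "class")]
        g = self.per_fold.groupby("class")[metrics]
        mean, sd = g.mean(), g.std(ddof=1)
        out = pd.concat({"mean": mean, "sd": sd}, axis=1)
        return out.swaplevel(axis=1).sort_index(axis=1)

    def mean(self, metric: str, cls: int) -> float:
        sub = self.per_fold[self.per_fold["class"] == cls]
        return float(sub[metric].mean())

    def summary(self) -> str:
        agg = self.aggregate()
        lines = ["Cross-validation metrics, mean (SD) over fold evaluations",
                 "-" * 58]
        for cls in agg.index:
            vals = []
            for m in ("auroc", "auprc", "brier"):
                if (m, "mean") in agg.columns:
                    vals.append(f"{m} {agg.loc[cls, (m, 'mean')]:.3f} "
                                f"({agg.loc[cls, (m, 'sd')]:.3f})")
            lines.append(f"class {cls}: " + ", ".join(vals))
        if self.n_folds_skipped:
            lines.append(f"folds skipped (missing class): {self.n_folds_skipped}")
        return "\n".join(lines)


def _fold_metrics(res, X_te, y_te) -> list[dict]:
    proba = res.predict_proba3(X_te)
    point = res.point_predict(X_te)
    brier, _ = brier_calibration(proba, y_te)
    rows = []
    for c in range(3):
        yb = (y_te == c).astype(int)
        if yb.min() == yb.max():
            continue
        tpr, ppv, f05 = tpr_ppv_f05(point == c, yb.astype(bool))
        rows.append({"class": c, "auroc": auroc(proba[:, c], yb),
                     "auprc": auprc(proba[:, c], yb), "brier": brier[c],
                     "tpr": tpr, "ppv": ppv, "f05": f05})
    return rows


def run_cv(plan: CVPlan, spec: ModelSpec, features, labels,
           columns: list[str] | None = None) -> MetricsReport:
    """Fit/evaluate ``spec`` under the CV plan; imputation and cutoffs are
    refitted within each training fold."""
    X = features.X if isinstance(features, FeatureMatrix) else features
    y = np.asarray(labels).astype(int)
    if columns is not None:
        X = X[list(columns)]
    rows, skipped = [], 0
    needed = {0, 1, 2} if spec.setup != "two_way" else {1}
    for k, (tr, te) in enumerate(plan.splitter().split(X, y)):
        repeat, fold = divmod(k, plan.n_folds)
        if not needed <= set(np.unique(y[tr])):
            skipped += 1
            logger.warning("fold %d/%d skipped: required class missing",
                           repeat, fold)
            continue
        res = TrajectoryClassifier(X.iloc[tr], y[tr], spec=spec).fit()
        for r in _fold_metrics(res, X.iloc[te], y[te]):
            rows.append({"repeat": repeat, "fold": fold, **r})
    return MetricsReport(pd.DataFrame(rows), n_folds_skipped=skipped)


def feature_subset_experiment(features, labels, modes=("all", "top15",
                                                       "nee_max_only"),
                              plan: CVPlan | None = None,
                              spec: ModelSpec | None = None,
                              top_k: int = 15) -> dict[str, MetricsReport]:
    """CV the multiclass GBM on nested feature subsets.

    ``top15`` selects the ``top_k`` features by mean absolute attribution of
    a model fitted on the training fold only (no leakage into the held-out
    fold); ``nee_max_only`` keeps just the maximum norepinephrine
    equivalence.
    """
    from .explain import explain

    X = features.X if isinstance(features, FeatureMatrix) else features
    y = np.asarray(labels).astype(int)
    plan = plan or CVPlan(n_folds=5, n_repeats=1)
    spec = spec or ModelSpec(architecture="gbm", setup="multiclass")
    if "nee_max_only" in modes and "nee_max" not in X.columns:
        raise DataError("nee_max column required for the NEE(max)-only mode")
    out: dict[str, MetricsReport] = {}
    for mode in modes:
        rows, skipped = [], 0
        for k, (tr, te) in enumerate(plan.splitter().split(X, y)):
            repeat, fold = divmod(k, plan.n_folds)
            if len(np.unique(y[tr])) < 3:
                skipped += 1
                continue
            if mode == "all":
                cols = list(X.columns)
            elif mode == "nee_max_only":
                cols = ["nee_max"]
            elif mode == "top15":
                full = TrajectoryClassifier(X.iloc[tr], y[tr], spec=spec).fit()
                cols = explain(full, X.iloc[tr]).top_features_overall(top_k)
            else:
                raise ConfigurationError(f"unknown subset mode {mode!r}")
            res = TrajectoryClassifier(X.iloc[tr][cols], y[tr], spec=spec).fit()
            for r in _fold_metrics(res, X.iloc[te][cols], y[te]):
                rows.append({"repeat": repeat, "fold": fold, **r})
        out[mode] = MetricsReport(pd.DataFrame(rows), n_folds_skipped=skipped)
    return out


def split_development_set(labels, train_frac: float = 0.8, seed: int = 0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified training/calibration split of the development set
    (default 80/20); returns (train_idx, calibration_idx)."""
    y = np.asarray(labels).astype(int)
    if not 0 < train_frac < 1:
        raise ConfigurationError("train_frac must be in (0, 1)")
    n_splits = max(2, int(round(1 / (1 - train_frac))))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    tr, cal = next(iter(skf.split(np.zeros(len(y)), y)))
    return tr, cal


DEFAULT_PIPELINE_CONFIG: dict = {
    "sim": {"n_patients": 2000, "seed": 0, "ineligible_fraction": 0.1},
    "registry": None,  # path to a registry YAML; default registry otherwise
    "model": {"architecture": "gbm", "setup": "multiclass"},
    "split": {"train_frac": 0.6, "cal_frac": 0.2, "seed": 0},
    "conformal": {"eps": {0: 0.25, 1: 0.25, 2: 0.15}},
}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict | None = None, out_dir=None,
                 seed: int | None = None) -> dict:
    """Execute the seven pipeline stages and write tables + manifest.

    Returns a dict with the key artefacts (cohort, labels, features, fitted
    results, conformal report) for programmatic use.
    """
    cfg = json.loads(json.dumps(DEFAULT_PIPELINE_CONFIG))
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    if seed is not None:
        cfg["sim"]["seed"] = seed
        cfg["split"]["seed"] = seed
    if cfg.get("registry") is not None:
        registry = FeatureRegistry.from_yaml(cfg["registry"])
    else:
        registry = default_registry()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    stages: list[dict] = []

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            stages.append({"stage": name,
                           "seconds": round(time.perf_counter() - t0, 3),
                           **counts})
        return done

    d = stage("simulate")
    sim_cfg = SimConfig(**cfg["sim"])
    bundles, truth = generate(sim_cfg)
    d(n_patients=len(bundles))

    d = stage("cohort")
    cohort = build_cohort(bundles)
    d(n_eligible=int((~cohort["excluded"]).sum()),
      n_excluded=int(cohort["excluded"].sum()))

    d = stage("label")
    labeled, class_summary = label_cohort(cohort, bundles)
    d(**{f"n_class_{int(r['trajectory'])}": int(r['count'])
         for _, r in class_summary.iterrows()})

    d = stage("featurize")
    matrix = build_matrix(labeled, bundles, registry)
    elig = labeled[~labeled["excluded"]].set_index("patient_id")
    y = elig.loc[matrix.patient_ids, "trajectory"].to_numpy(dtype=int)
    d(n_rows=len(matrix.X), n_columns=matrix.X.shape[1])

    # development/test split, then train/calibration inside development
    d = stage("train")
    rng_seed = int(cfg["split"]["seed"])
    test_frac = 1.0 - cfg["split"]["train_frac"] - cfg["split"]["cal_frac"]
    dev_idx, test_idx = split_development_set(y, 1.0 - test_frac, rng_seed)
    y_dev = y[dev_idx]
    tr_rel, cal_rel = split_development_set(
        y_dev, cfg["split"]["train_frac"] /
        (cfg["split"]["train_frac"] + cfg["split"]["cal_frac"]), rng_seed)
    tr_idx, cal_idx = dev_idx[tr_rel], dev_idx[cal_rel]
    spec = ModelSpec(seed=rng_seed, **cfg["model"])
    res = TrajectoryClassifier(matrix.X.iloc[tr_idx], y[tr_idx], spec=spec).fit()
    d(n_train=len(tr_idx), n_calibration=len(cal_idx), n_test=len(test_idx))

    d = stage("conformal_eval")
    conf = cp.MondrianConformal(res).calibrate(matrix.X.iloc[cal_idx],
                                               y[cal_idx])
    eps = {int(k): float(v) for k, v in cfg["conformal"]["eps"].items()}
    P = conf.pvalues(matrix.X.iloc[test_idx])
    report = cp.efficiency_validity(P, y[test_idx], eps)
    region_table = conf.predict(matrix.X.iloc[test_idx], eps=eps)
    member = cp.regions_from_pvalues(P, eps)
    breakdown = cp.multiple_breakdown(member, y[test_idx])
    d(n_test=len(test_idx))

    d = stage("report")
    proba_test = res.predict_proba3(matrix.X.iloc[test_idx])
    test_metrics = {}
    for c in range(3):
        yb = (y[test_idx] == c).astype(int)
        if yb.min() != yb.max():
            test_metrics[f"auroc_class_{c}"] = auroc(proba_test[:, c], yb)
    point = res.point_predict(matrix.X.iloc[test_idx])
    test_metrics["point_error_rate"] = float(np.mean(point != y[test_idx]))
    test_metrics["efficiency"] = report["efficiency"]
    manifest = {
        "config": cfg, "config_hash": _config_hash(cfg),
        "stages": stages, "test_metrics": test_metrics,
        "class_summary": class_summary.to_dict(orient="records"),
    }
    if out_dir is not None:
        write_bundles(bundles, out_dir / "data", ground_truth=truth)
        labeled.to_csv(out_dir / "labeled_cohort.csv", index=False)
        matrix.X.to_csv(out_dir / "features.csv")
        matrix.provenance.to_csv(out_dir / "provenance.csv", index=False)
        report["tally"].to_csv(out_dir / "region_tally.csv", index=False)
        breakdown.to_csv(out_dir / "multiple_breakdown.csv", index=False)
        report["error_curve"].to_csv(out_dir / "cp_error_curve.csv", index=False)
        report["label_distribution_curve"].to_csv(
            out_dir / "cp_label_distribution.csv", index=False)
        region_table.to_csv(out_dir / "regions.csv")
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    d()
    manifest["stages"] = stages
    return {"bundles": bundles, "truth": truth, "cohort": labeled,
            "class_summary": class_summary, "matrix": matrix, "labels": y,
            "results": res, "conformal": conf, "cp_report": report,
            "region_table": region_table, "manifest": manifest,
            "split": {"train": tr_idx, "calibration": cal_idx,
                      "test": test_idx}}
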