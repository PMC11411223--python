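"""Feature engineering over the 24-h window between identification and enrollment.

For every eligible patient, each registered time-varying variable is reduced
to four summaries — maximum, minimum, median and coefficient of variation
(sample SD / mean) — over the half-open window ``[t_sepsis, t_enroll)``.
Static variables (demographics) are carried through unchanged, and urine
output additionally contributes a window total.  The combined vasopressor
burden enters as a derived time-varying variable, the norepinephrine
equivalence (NEE, μg/kg/min): the sum over active infusions of the drug
rate converted to norepinephrine-equivalent units, sampled on the hourly
observation grid covering the window.

Missingness is explicit: a summary that cannot be computed (no measurement
in the window; CV of fewer than two values or of a zero-mean window) is NaN
and flagged in the missing mask, never silently zero.  Mean imputation is a
separate, train-fold-only step so cross-validation stays leakage-free.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import ContractViolation, DataError
from .synthetic import BundleSet

__all__ = ["FeatureRegistry", "FeatureMatrix", "MeanImputer",
           "default_registry", "filter_outliers", "compute_nee",
           "summarize_window", "build_matrix", "fit_mean_imputer",
           "apply_imputer", "NEE_GRID_STEP_HOURS"]

logger = logging.getLogger(__name__)

SUMMARIES = ("max", "min", "median", "cv")
NEE_GRID_STEP_HOURS = 1.0


@dataclass(frozen=True)
class FeatureRegistry:
    """Declarative description of the feature matrix (see data/registry.yaml)."""

    static_features: tuple[tuple[str, str], ...]  # (name, source column)
    timevarying_features: tuple[tuple[str, str, str], ...]  # (name, variable, units)
    outlier_ranges: dict[str, tuple[float, float]]
    nee_conversion: dict[str, float]
    window_total_features: tuple[str, ...] = ()
    summaries: tuple[str, ...] = SUMMARIES

    def __post_init__(self):
        names = [n for n, _ in self.static_features]
        names += [n for n, _, _ in self.timevarying_features]
        if len(set(names)) != len(names):
            raise DataError("feature names must be unique")
        for v, (lo, hi) in self.outlier_ranges.items():
            if not lo < hi:
                raise DataError(f"outlier bounds for {v!r} need lower < upper")

    @property
    def column_names(self) -> list[str]:
        cols = [n for n, _ in self.static_features]
        for name, _, _ in self.timevarying_features:
            cols += [f"{name}_{s}" for s in self.summaries]
        cols += [f"{name}_total" for name in self.window_total_features]
        return cols

    @classmethod
    def from_yaml(cls, source) -> "FeatureRegistry":
        if hasattr(source, "read"):
            cfg = yaml.safe_load(source)
        else:
            with open(source) as fh:
                cfg = yaml.safe_load(fh)
        return cls(
            static_features=tuple((k, v) for k, v in
                                  cfg["static_features"].items()),
            timevarying_features=tuple(
                (k, v["variable"], v.get("units", ""))
                for k, v in cfg["timevarying_features"].items()),
            outlier_ranges={k: (float(v[0]), float(v[1]))
                            for k, v in cfg.get("outlier_ranges", {}).items()},
            nee_conversion={k: float(v) for k, v in
                            cfg.get("nee_conversion", {}).items()},
            window_total_features=tuple(cfg.get("window_total_features", ())),
        )


def default_registry() -> FeatureRegistry:
    """The registry shipped with the package (~145 columns)."""
    ref = resources.files("sepsistraj.data") / "registry.yaml"
    with ref.open() as fh:
        return FeatureRegistry.from_yaml(fh)


@dataclass
class FeatureMatrix:
    """Patients × named features; NaN cells are missing (see ``mask``)."""

    X: pd.DataFrame  # indexed by patient_id
    provenance: pd.DataFrame  # column, source_variable, summary

    @property
    def patient_ids(self) -> pd.Index:
        return self.X.index

    @property
    def mask(self) -> pd.DataFrame:
        return self.X.isna()

    def subset_columns(self, columns) -> "FeatureMatrix":
        prov = self.provenance[self.provenance["column"].isin(columns)]
        return FeatureMatrix(self.X[list(columns)], prov.reset_index(drop=True))


def filter_outliers(observations: pd.DataFrame,
                    registry: FeatureRegistry) -> pd.DataFrame:
    """Drop records outside the registered physiologic bounds (closed interval)."""
    if len(observations) == 0:
        return observations
    vals = observations["value"].to_numpy(dtype=float)
    var = observations["variable"]
    keep = np.ones(len(observations), dtype=bool)
    removed: dict[str, int] = {}
    for v in pd.unique(var):
        m = (var == v).to_numpy()
        bounds = registry.outlier_ranges.get(str(v))
        if bounds is None:
            warnings.warn(f"no outlier bounds registered for variable {v!r}; "
                          "passing through", stacklevel=2)
            continue
        lo, hi = bounds
        bad = m & ~((vals >= lo) & (vals <= hi))
        if bad.any():
            removed[str(v)] = int(bad.sum())
            keep &= ~bad
    for v, k in sorted(removed.items()):
        logger.info("outlier filter: removed %d %s record(s)", k, v)
    return observations[keep]


def compute_nee(infusions: pd.DataFrame, weight_kg: float,
                at: np.ndarray, registry: FeatureRegistry | None = None
                ) -> np.ndarray:
    """Norepinephrine-equivalent dose (μg/kg/min) at each time in ``at``.

    A record is active on ``[start, end)``.  Weight-based rates are already
    per-kg; absolute μg/min rates are divided by body weight; vasopressin
    U/min uses its registered factor directly.
    """
    conv = (registry.nee_conversion if registry is not None
            else default_registry().nee_conversion)
    at = np.asarray(at, dtype=float)
    out = np.zeros_like(at)
    if len(infusions) == 0:
        return out
    unknown = sorted(set(infusions["drug_name"]) - set(conv))
    if unknown:
        raise DataError(f"unknown vasopressor drug(s) {unknown}; extend "
                        "the registry's nee_conversion table")
    for drug, rate, units, wb, s, e in zip(
            infusions["drug_name"], infusions["rate_value"],
            infusions["rate_units"], infusions["weight_based"],
            infusions["start_hours"], infusions["end_hours"]):
        if rate <= 0:
            continue
        per_kg = rate if (wb or units == "U/min") else rate / weight_kg
        contrib = per_kg * conv[drug]
        out[(at >= s) & (at < e)] += contrib
    return out


def summarize_window(values) -> dict[str, float]:
    """Four summaries of one variable's in-window measurements.

    CV uses the sample SD (n−1); it is NaN for fewer than two measurements
    or a zero-mean window, and all four summaries are NaN for an empty
    window.
    """
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return {s: np.nan for s in SUMMARIES}
    out = {"max": float(x.max()), "min": float(x.min()),
           "median": float(np.median(x)), "cv": np.nan}
    mean = float(x.mean())
    if x.size >= 2 and mean != 0.0:
        out["cv"] = float(x.std(ddof=1) / mean)
    return out


def _codes(col: pd.Series) -> tuple[np.ndarray, pd.Index]:
    if isinstance(col.dtype, pd.CategoricalDtype):
        return col.cat.codes.to_numpy(), col.cat.categories
    codes, cats = pd.factorize(col)
    return codes, pd.Index(cats)


def _nee_window_grid(t_sepsis: float, t_enroll: float) -> np.ndarray:
    return np.arange(t_sepsis + NEE_GRID_STEP_HOURS / 2, t_enroll,
                     NEE_GRID_STEP_HOURS)


def build_matrix(cohort: pd.DataFrame, bundles: BundleSet,
                 registry: FeatureRegistry | None = None) -> FeatureMatrix:
    """One row per eligible patient, columns per the registry.

    Row order follows the cohort's eligible rows; column order is
    deterministic (statics, then per-variable summary blocks, then window
    totals).
    """
    if registry is None:
        registry = default_registry()
    eligible = cohort[~cohort["excluded"]]
    pid_order = eligible["patient_id"].tolist()
    missing = set(pid_order) - set(map(str, bundles.patients["patient_id"]))
    if missing:
        raise DataError(f"patients missing from bundles: {sorted(missing)[:5]}")

    win = eligible.set_index("patient_id")[["t_sepsis", "t_enroll"]]

    # fused window restriction + outlier filter on integer codes; avoids
    # materialising per-row strings or full-table copies on large cohorts
    obs = bundles.observations
    pid_codes, pid_cats = _codes(obs["patient_id"])
    ts = win["t_sepsis"].reindex(pid_cats).to_numpy(dtype=float)[pid_codes]
    te = win["t_enroll"].reindex(pid_cats).to_numpy(dtype=float)[pid_codes]
    t = obs["time_hours"].to_numpy(dtype=float)
    keep = (t >= ts) & (t < te)  # NaN windows (ineligible) drop out
    del ts, te, t
    var_codes, var_cats = _codes(obs["variable"])
    lo = np.full(len(var_cats), -np.inf)
    hi = np.full(len(var_cats), np.inf)
    for i, v in enumerate(var_cats):
        bounds = registry.outlier_ranges.get(str(v))
        if bounds is None:
            warnings.warn(f"no outlier bounds registered for variable "
                          f"{v!r}; passing through", stacklevel=2)
        else:
            lo[i], hi[i] = bounds
    vals = obs["value"].to_numpy(dtype=float)
    keep &= (vals >= lo[var_codes]) & (vals <= hi[var_codes])
    small = pd.DataFrame({
        "patient_id": pd.Categorical.from_codes(pid_codes[keep],
                                                categories=pid_cats),
        "variable": pd.Categorical.from_codes(var_codes[keep],
                                              categories=var_cats),
        "value": vals[keep],
    })
    del pid_codes, var_codes, vals, keep

    g = (small.groupby(["patient_id", "variable"], observed=True)["value"]
         .agg(["max", "min", "median", "mean", "std", "count", "sum"]))

    def stat_frame(stat: str) -> pd.DataFrame:
        return g[stat].unstack("variable").reindex(pid_order)

    stats = {s: stat_frame(s)
             for s in ("max", "min", "median", "mean", "std", "count", "sum")}

    # derived NEE series per patient, summarised like any other variable
    nee_rows = {}
    inf_groups = bundles.infusions.groupby("patient_id", observed=True).indices
    weights = bundles.patients.set_index("patient_id")["weight_kg"]
    for pid in pid_order:
        idx = inf_groups.get(pid)
        inf = (bundles.infusions.iloc[idx] if idx is not None
               else bundles.infusions.iloc[0:0])
        grid = _nee_window_grid(win.at[pid, "t_sepsis"], win.at[pid, "t_enroll"])
        series = compute_nee(inf, float(weights[pid]), grid, registry)
        nee_rows[pid] = summarize_window(series)
    nee_df = pd.DataFrame.from_dict(nee_rows, orient="index").reindex(pid_order)

    pat = bundles.patients.set_index("patient_id").loc[pid_order]
    cols: dict[str, np.ndarray] = {}
    prov: list[tuple[str, str, str]] = []
    for name, source in registry.static_features:
        if name == "sex_male":
            cols[name] = (pat["sex"].astype(str) == "M").to_numpy(dtype=float)
        elif source == "derived" and name == "onset_from_admission_hours":
            cols[name] = (win.loc[pid_order, "t_sepsis"].to_numpy()
                          - pat["icu_in"].to_numpy())
        else:
            if source not in pat.columns:
                raise DataError(f"static source column {source!r} not found")
            cols[name] = pat[source].to_numpy(dtype=float)
        prov.append((name, source, "static"))

    def var_stat(var: str, stat: str) -> np.ndarray:
        df = stats[stat]
        if var in df.columns:
            return df[var].to_numpy(dtype=float)
        return np.full(len(pid_order), np.nan)

    for name, var, _units in registry.timevarying_features:
        if var == "nee":
            block = {s: nee_df[s].to_numpy(dtype=float) for s in SUMMARIES}
        else:
            mean = var_stat(var, "mean")
            sd = var_stat(var, "std")
            cnt = var_stat(var, "count")
            with np.errstate(divide="ignore", invalid="ignore"):
                cv = np.where((cnt >= 2) & (mean != 0.0), sd / mean, np.nan)
            block = {"max": var_stat(var, "max"), "min": var_stat(var, "min"),
                     "median": var_stat(var, "median"), "cv": cv}
        for s in registry.summaries:
            cols[f"{name}_{s}"] = block[s]
            prov.append((f"{name}_{s}", var, s))

    for name in registry.window_total_features:
        var = dict((n, v) for n, v, _ in registry.timevarying_features)[name]
        cols[f"{name}_total"] = var_stat(var, "sum") if var != "nee" else \
            np.full(len(pid_order), np.nan)
        # an empty window must stay missing, not zero
        cnt = var_stat(var, "count")
        cols[f"{name}_total"][cnt == 0] = np.nan
        prov.append((f"{name}_total", var, "total"))

    X = pd.DataFrame(cols, index=pd.Index(pid_order, name="patient_id"))
    X = X.replace([np.inf, -np.inf], np.nan)
    provenance = pd.DataFrame(prov, columns=["column", "source_variable",
                                             "summary"])
    return FeatureMatrix(X=X, provenance=provenance)


class MeanImputer:
    """Column-mean imputation fitted on training rows only.

    Columns that are entirely missing in training are filled with 0 and
    listed in ``zero_filled_``.
    """

    def __init__(self):
        self.means_: pd.Series | None = None
        self.zero_filled_: list[str] = []

    def fit(self, X: pd.DataFrame) -> "MeanImputer":
        self.means_ = X.mean(axis=0, skipna=True)
        self.zero_filled_ = [c for c in X.columns
                             if not np.isfinite(self.means_[c])]
        self.means_ = self.means_.fillna(0.0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.means_ is None:
            raise ContractViolation("imputer used before fitting")
        return X.fillna(self.means_)


def fit_mean_imputer(matrix: FeatureMatrix | pd.DataFrame) -> MeanImputer:
    X = matrix.X if isinstance(matrix, FeatureMatrix) else matrix
    return MeanImputer().fit(X)


def apply_imputer(imputer: MeanImputer,
                  matrix: FeatureMatrix | pd.DataFrame):
    if isinstance(matrix, FeatureMatrix):
        return FeatureMatrix(imputer.transform(matrix.X), matrix.provenance)
    return imputer.transform(matrix)
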