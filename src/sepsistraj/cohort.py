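"""Sepsis-3 onset detection and cohort inclusion/exclusion.

Onset is anchored on two clocks:

* ``t_suspicion`` — clinical suspicion of infection, the earlier timestamp of
  a qualifying antibiotic/culture pair: a culture obtained within 24 h after
  an IV antibiotic, or an antibiotic ordered within 72 h after a culture;
* ``t_sofa`` — the earliest time at which the SOFA total score rises by
  ≥2 points relative to the minimum score in the preceding 24 h.

If both exist and ``t_suspicion − 24 h ≤ t_sofa ≤ t_suspicion + 12 h``, the
sepsis onset is ``t_sepsis = min(t_suspicion, t_sofa)``; otherwise the patient
is not diagnosed as septic.  Enrollment is simulated at ``t_sepsis + 24 h``
and the trajectory outcome window ends 48 h after enrollment.

Inclusion requires: a detected onset within 24 h of ICU admission, age ≥18,
vasopressor initiation within 24 h of onset, survival and an ICU stay of at
least 24 h, first ICU admission only.  Criteria are evaluated in that fixed
order so each excluded patient reports exactly one reason.

All window inequalities are closed at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .synthetic import BundleSet, EventBundle

__all__ = [
    "OnsetResult", "CohortRow", "EXCLUSION_REASONS",
    "compute_suspicion_time", "compute_sofa_rise_time", "compute_sepsis_onset",
    "detect_onset", "apply_inclusion_exclusion", "build_cohort",
]

ENROLL_DELAY_HOURS = 24.0
OUTCOME_WINDOW_HOURS = 48.0

EXCLUSION_REASONS = ("no_onset", "late_onset", "age", "no_vasopressor_24h",
                     "early_death", "short_icu_stay", "not_first_icu_stay")


@dataclass(frozen=True)
class OnsetResult:
    t_suspicion: float | None
    t_sofa: float | None
    t_sepsis: float | None
    reason: str  # ok | no_suspicion | no_sofa_rise | window_violated


@dataclass
class CohortRow:
    patient_id: str
    t_sepsis: float | None
    t_enroll: float | None
    label_window_end: float | None
    trajectory: int | None = None
    excluded: bool = False
    exclusion_reason: str | None = None


def compute_suspicion_time(antibiotics, cultures) -> float | None:
    """Earliest ``min(a, c)`` over qualifying antibiotic/culture pairs.

    A pair qualifies when ``a ≤ c ≤ a + 24`` (culture within 24 h after the
    antibiotic) or ``c ≤ a ≤ c + 72`` (antibiotic within 72 h after the
    culture).  Returns ``None`` when no pair qualifies.
    """
    a = np.sort(np.asarray(list(antibiotics), dtype=float))
    c = np.sort(np.asarray(list(cultures), dtype=float))
    if a.size == 0 or c.size == 0:
        return None
    diff = c[None, :] - a[:, None]  # c - a for each pair
    ok = ((diff >= 0.0) & (diff <= 24.0)) | ((diff <= 0.0) & (diff >= -72.0))
    if not ok.any():
        return None
    earliest = np.minimum(a[:, None], c[None, :])
    return float(earliest[ok].min())


def compute_sofa_rise_time(sofa: pd.DataFrame) -> float | None:
    """Earliest time ``t`` with ``score(t) − min(score over [t−24, t)) ≥ 2``."""
    if len(sofa) == 0:
        return None
    df = sofa.sort_values("time_hours", kind="stable")
    t = df["time_hours"].to_numpy(dtype=float)
    s = df["total_score"].to_numpy(dtype=float)
    for i in range(1, len(t)):
        window = (t >= t[i] - 24.0) & (t < t[i])
        if window.any() and s[i] - s[window].min() >= 2.0:
            return float(t[i])
    return None


def compute_sepsis_onset(t_suspicion: float | None,
                         t_sofa: float | None) -> OnsetResult:
    """Combine the two clocks under the ±(24 h, 12 h) pairing window."""
    if t_suspicion is None:
        return OnsetResult(None, t_sofa, None, "no_suspicion")
    if t_sofa is None:
        return OnsetResult(t_suspicion, None, None, "no_sofa_rise")
    if t_suspicion - 24.0 <= t_sofa <= t_suspicion + 12.0:
        return OnsetResult(t_suspicion, t_sofa,
                           min(t_suspicion, t_sofa), "ok")
    return OnsetResult(t_suspicion, t_sofa, None, "window_violated")


def detect_onset(bundle: EventBundle) -> OnsetResult:
    return compute_sepsis_onset(
        compute_suspicion_time(bundle.antibiotics, bundle.cultures),
        compute_sofa_rise_time(bundle.sofa))


def apply_inclusion_exclusion(bundle: EventBundle,
                              onset: OnsetResult) -> CohortRow:
    """Apply the criteria in fixed order; excluded rows carry one reason."""
    pid = bundle.patient_id
    if bundle.icu_in is None or not np.isfinite(bundle.icu_in) \
            or bundle.icu_out is None or not np.isfinite(bundle.icu_out):
        raise DataError(f"patient {pid}: missing ICU admission timestamps")
    if bundle.weight_kg is None or not np.isfinite(bundle.weight_kg):
        raise DataError(f"patient {pid}: missing weight")

    def excluded(reason: str) -> CohortRow:
        t = onset.t_sepsis
        return CohortRow(pid, t, None, None, excluded=True,
                         exclusion_reason=reason)

    if onset.t_sepsis is None:
        return excluded("no_onset")
    t = onset.t_sepsis
    if t > bundle.icu_in + 24.0:
        return excluded("late_onset")
    if bundle.age_years < 18:
        return excluded("age")
    inf = bundle.infusions
    starts = inf.loc[inf["rate_value"] > 0, "start_hours"].to_numpy(dtype=float)
    if not ((starts >= t) & (starts <= t + 24.0)).any():
        return excluded("no_vasopressor_24h")
    if bundle.death_time is not None and bundle.death_time < t + 24.0:
        return excluded("early_death")
    if bundle.icu_out - bundle.icu_in < 24.0:
        return excluded("short_icu_stay")
    return CohortRow(pid, t, t + ENROLL_DELAY_HOURS,
                     t + ENROLL_DELAY_HOURS + OUTCOME_WINDOW_HOURS)


def build_cohort(bundles: BundleSet) -> pd.DataFrame:
    """One row per patient stay with onset, enrollment and exclusion status.

    Only the earliest ICU admission per ``patient_id`` is eligible; any later
    stay rows are excluded with reason ``not_first_icu_stay``.
    """
    patients = bundles.patients
    first_idx = patients.groupby("patient_id")["icu_in"].idxmin()
    is_first = patients.index.isin(first_idx)
    rows = []
    light = ("infusions", "antibiotics", "cultures", "sofa")
    for i, pid in enumerate(patients["patient_id"]):
        if not is_first[i]:
            rows.append(CohortRow(pid, None, None, None, excluded=True,
                                  exclusion_reason="not_first_icu_stay"))
            continue
        b = bundles.bundle(pid, tables=light)
        onset = detect_onset(b)
        row = apply_inclusion_exclusion(b, onset)
        rows.append(row)
    out = pd.DataFrame([{
        "patient_id": r.patient_id,
        "t_sepsis": np.nan if r.t_sepsis is None else r.t_sepsis,
        "t_enroll": np.nan if r.t_enroll is None else r.t_enroll,
        "label_window_end": (np.nan if r.label_window_end is None
                             else r.label_window_end),
        "trajectory": np.nan,
        "excluded": r.excluded,
        "exclusion_reason": r.exclusion_reason or "",
    } for r in rows])
    return out
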