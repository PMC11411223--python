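"""Synthetic ICU event-stream generator with planted sepsis trajectories.

Real trajectory-enrichment cohorts live in credentialed-access clinical
databases, so every downstream stage of this package (onset detection,
trajectory labeling, feature building, modelling, conformal prediction) is
exercised against a seeded simulator instead.  The simulator plants, per
patient, one of three disease-progression classes —

* ``0`` rapid death: death within 48 h of enrollment, sustained high
  norepinephrine-equivalent (NEE) dose, tachycardia, hypotension;
* ``1`` persistent ill: ongoing vasopressor need throughout the 48-h
  outcome window at a moderate sustained NEE;
* ``2`` recovery: vasopressor liberation within 48 h of enrollment,
  maintained for at least 24 h, with a weaning NEE trajectory —

and emits the raw event tables a hospital data warehouse would provide:
observations (vitals and labs), vasopressor infusion intervals, antibiotic
administrations, culture acquisitions, a SOFA total-score series, and
admission/discharge/death timestamps.  Antibiotic, culture and SOFA events
are placed so that the Sepsis-3 onset rules recover the planted onset time
exactly for every eligible patient, which gives the test suite a ground-truth
oracle.

Time is real-valued hours since a per-patient epoch (48 h before ICU
admission, so all event times are non-negative); all generated times are
quantized to milli-hours so that ISO-8601 serialisation round-trips exactly.
Class-conditional dynamics are piecewise-linear mean trajectories plus
Gaussian noise; all dynamics parameters live in :class:`SimConfig`, not in
code.
"""

from __future__ import annotations

from collections.abc import Iterator, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "RAPID_DEATH",
    "PERSISTENT_ILL",
    "RECOVERY",
    "CLASS_NAMES",
    "ClassDynamics",
    "SimConfig",
    "EventBundle",
    "BundleSet",
    "generate",
]

RAPID_DEATH, PERSISTENT_ILL, RECOVERY = 0, 1, 2
CLASS_NAMES = {RAPID_DEATH: "rapid_death", PERSISTENT_ILL: "persistent_ill", RECOVERY: "recovery"}

#: ICU admission happens 48 h after the per-patient epoch, leaving room for
#: pre-ICU events while keeping all times non-negative.
ICU_IN_HOURS = 48.0

_PERTURBATIONS = ("age", "early_death", "short_icu_stay", "late_vasopressor")


_MS_PER_HOUR = 3_600_000.0


def _q(x):
    """Quantize times to whole milliseconds, in the exact float form the
    ISO-8601 file round trip reproduces (``round(h·3.6e6)/3.6e6``).
    Idempotent, so stored times survive write→read bitwise."""
    return np.round(np.asarray(x, dtype=float) * _MS_PER_HOUR) / _MS_PER_HOUR


@dataclass(frozen=True)
class ClassDynamics:
    """Class-conditional mean dynamics inside and after the feature window.

    NEE follows ``nee_level + nee_slope * (t - onset)`` (rapid death /
    persistent ill) or a linear wean from ``nee_level`` down to ~0.04
    μg/kg/min at liberation (recovery).  Vital/lab levels apply from onset
    onwards; before onset patients sit at population baselines.
    """

    nee_level: float  # μg/kg/min at onset
    nee_slope: float  # μg/kg/min per hour
    hr_level: float  # bpm
    sbp_level: float  # mm Hg
    lactate_level: float  # mmol/L
    urine_rate: float  # mL/h
    nee_sd: float = 0.05
    hr_sd: float = 8.0
    sbp_sd: float = 10.0
    lactate_sd: float = 0.6
    urine_sd: float = 10.0


#: Levels chosen so the three classes are separable primarily through the
#: NEE trajectory (sustained high & rising / sustained moderate / weaning),
#: with supporting but weaker vital-sign signal, mirroring the qualitative
#: trends of real sepsis trajectory cohorts.
DEFAULT_EFFECTS: dict[int, ClassDynamics] = {
    RAPID_DEATH: ClassDynamics(
        nee_level=0.50, nee_slope=0.006, hr_level=106.0, sbp_level=94.0,
        lactate_level=3.6, urine_rate=18.0,
        nee_sd=0.10, hr_sd=10.0, sbp_sd=12.0, lactate_sd=1.0, urine_sd=18.0),
    PERSISTENT_ILL: ClassDynamics(
        nee_level=0.42, nee_slope=0.0, hr_level=94.0, sbp_level=102.0,
        lactate_level=2.8, urine_rate=30.0,
        nee_sd=0.10, hr_sd=10.0, sbp_sd=12.0, lactate_sd=1.0, urine_sd=18.0),
    RECOVERY: ClassDynamics(
        nee_level=0.26, nee_slope=0.0, hr_level=88.0, sbp_level=110.0,
        lactate_level=1.9, urine_rate=55.0,
        nee_sd=0.10, hr_sd=10.0, sbp_sd=12.0, lactate_sd=1.0, urine_sd=18.0),
}

#: Between-patient SD of the per-patient NEE severity offset; creates the
#: class overlap real cohorts show (discrimination well below perfect).
NEE_BETWEEN_PATIENT_SD = 0.09

# population baselines for non-signal lab variables:
# name -> (mean, between-patient SD, within-patient SD, low clip, high clip)
LAB_BASELINES: dict[str, tuple[float, float, float, float, float]] = {
    "creatinine": (1.2, 0.5, 0.15, 0.2, 15.0),
    "bun": (25.0, 10.0, 3.0, 2.0, 180.0),
    "wbc": (12.0, 4.0, 1.5, 0.1, 150.0),
    "hemoglobin": (10.5, 1.5, 0.5, 3.0, 22.0),
    "hematocrit": (32.0, 4.5, 1.5, 10.0, 65.0),
    "platelets": (180.0, 70.0, 15.0, 5.0, 1500.0),
    "sodium": (138.0, 4.0, 1.5, 110.0, 175.0),
    "potassium": (4.2, 0.5, 0.25, 1.5, 9.0),
    "chloride": (104.0, 5.0, 1.5, 70.0, 140.0),
    "bicarbonate": (22.0, 4.0, 1.2, 5.0, 50.0),
    "glucose": (140.0, 40.0, 20.0, 20.0, 1000.0),
    "bilirubin": (1.5, 1.2, 0.3, 0.1, 60.0),
    "albumin": (3.0, 0.5, 0.15, 0.5, 6.0),
    "arterial_ph": (7.36, 0.05, 0.03, 6.7, 7.8),
    "pao2": (95.0, 25.0, 10.0, 20.0, 600.0),
    "paco2": (40.0, 7.0, 3.0, 10.0, 150.0),
    "aptt": (38.0, 12.0, 4.0, 15.0, 200.0),
    "pt_inr": (1.4, 0.4, 0.1, 0.5, 15.0),
    "calcium": (8.4, 0.7, 0.25, 4.0, 16.0),
    "magnesium": (2.0, 0.3, 0.12, 0.5, 8.0),
    "phosphate": (3.5, 1.0, 0.3, 0.5, 15.0),
    "alt": (45.0, 30.0, 8.0, 2.0, 5000.0),
    "ast": (60.0, 40.0, 10.0, 2.0, 5000.0),
    "troponin": (0.1, 0.15, 0.04, 0.0, 50.0),
}

VITAL_VARIABLES = (
    "heart_rate", "sbp", "dbp", "map", "resp_rate", "spo2",
    "temperature", "gcs", "urine_output",
)
LAB_VARIABLES = ("lactate",) + tuple(LAB_BASELINES)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation run.

    ``class_priors`` defaults to the rapid-death / persistent-ill / recovery
    prevalences of a large North-American sepsis-with-vasopressors cohort
    (4.0% / 32.1% / 63.9%).  ``ineligible_fraction`` controls how many
    patients are generated with exactly one violated inclusion criterion so
    exclusion logic is exercised; set it to 0 for oracle round-trip tests.
    """

    n_patients: int
    class_priors: tuple[float, float, float] = (0.040, 0.321, 0.639)
    seed: int = 0
    horizon_hours: float = 168.0
    obs_interval_hours: float = 1.0
    lab_interval_hours: float = 6.0
    missingness_rate: float = 0.05
    effect_params: dict[int, ClassDynamics] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    ineligible_fraction: float = 0.10

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        p = np.asarray(self.class_priors, dtype=float)
        if p.shape != (3,) or (p < 0).any() or (p > 1).any():
            raise ConfigurationError("class_priors must be three probabilities")
        if abs(float(p.sum()) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_priors must sum to 1 (got {p.sum():.12f})")
        if self.horizon_hours < 72.0:
            raise ConfigurationError(
                "horizon_hours must be >= 72 (24-h feature window + 48-h "
                "outcome window)")
        if self.obs_interval_hours <= 0 or self.lab_interval_hours <= 0:
            raise ConfigurationError("observation intervals must be positive")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ConfigurationError("missingness_rate must be in [0, 1)")
        if not 0.0 <= self.ineligible_fraction <= 1.0:
            raise ConfigurationError("ineligible_fraction must be in [0, 1]")
        for c in (RAPID_DEATH, PERSISTENT_ILL, RECOVERY):
            if c not in self.effect_params:
                raise ConfigurationError(f"effect_params missing class {c}")


@dataclass
class EventBundle:
    """All raw event tables for one patient, times in hours since epoch."""

    patient_id: str
    age_years: float
    sex: str
    weight_kg: float
    icu_in: float
    icu_out: float
    death_time: float | None
    observations: pd.DataFrame  # time_hours, variable, value
    infusions: pd.DataFrame  # drug_name, rate_value, rate_units, weight_based, start_hours, end_hours
    antibiotics: np.ndarray  # administration times
    cultures: np.ndarray  # specimen acquisition times
    sofa: pd.DataFrame  # time_hours, total_score


class BundleSet(Sequence):
    """Column-oriented container over many patients' event tables.

    Stores one DataFrame per table kind (fast vectorised access for the
    feature engine) while behaving as a sequence of per-patient
    :class:`EventBundle` views for code written against single patients.
    """

    TABLE_NAMES = ("patients", "observations", "infusions", "antibiotics",
                   "cultures", "sofa")

    def __init__(self, patients: pd.DataFrame, observations: pd.DataFrame,
                 infusions: pd.DataFrame, antibiotics: pd.DataFrame,
                 cultures: pd.DataFrame, sofa: pd.DataFrame):
        self.patients = patients.reset_index(drop=True)
        self.observations = observations
        self.infusions = infusions
        self.antibiotics = antibiotics
        self.cultures = cultures
        self.sofa = sofa
        self._groups: dict[str, dict] = {}
        self._patient_pos: dict[str, int] | None = None

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in self.TABLE_NAMES}

    def __len__(self) -> int:
        return len(self.patients)

    def _rows(self, table: str, pid: str) -> pd.DataFrame:
        if table not in self._groups:
            df = getattr(self, table)
            self._groups[table] = (
                df.groupby("patient_id", observed=True, sort=False).indices)
        idx = self._groups[table].get(pid)
        df = getattr(self, table)
        if idx is None:
            return df.iloc[0:0]
        return df.iloc[idx]

    def bundle(self, patient_id: str,
               tables: tuple[str, ...] | None = None) -> EventBundle:
        """Per-patient view; ``tables`` restricts which event tables are
        materialised (the rest come back empty), a cheap path for stages
        that do not need the observation stream."""
        if self._patient_pos is None:
            self._patient_pos = {}
            for i, pid in enumerate(self.patients["patient_id"]):
                self._patient_pos.setdefault(pid, i)  # earliest stay row wins
        pos = self._patient_pos.get(patient_id)
        if pos is None:
            raise DataError(f"unknown patient_id {patient_id!r}")
        r = self.patients.iloc[pos]
        death = r["death_time"]

        def rows(table):
            if tables is not None and table not in tables:
                return getattr(self, table).iloc[0:0]
            return self._rows(table, patient_id)

        return EventBundle(
            patient_id=patient_id,
            age_years=float(r["age_years"]),
            sex=str(r["sex"]),
            weight_kg=float(r["weight_kg"]),
            icu_in=float(r["icu_in"]),
            icu_out=float(r["icu_out"]),
            death_time=None if pd.isna(death) else float(death),
            observations=rows("observations")
            .drop(columns="patient_id").reset_index(drop=True),
            infusions=rows("infusions")
            .drop(columns="patient_id").reset_index(drop=True),
            antibiotics=rows("antibiotics")["time_hours"].to_numpy(dtype=float),
            cultures=rows("cultures")["time_hours"].to_numpy(dtype=float),
            sofa=rows("sofa").drop(columns="patient_id").reset_index(drop=True),
        )

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        return self.bundle(self.patients["patient_id"].iloc[i])

    def __iter__(self) -> Iterator[EventBundle]:
        for pid in self.patients["patient_id"]:
            yield self.bundle(pid)

    @classmethod
    def from_bundles(cls, bundles: Sequence[EventBundle]) -> "BundleSet":
        pat_rows, obs, inf, abx, cul, sofa = [], [], [], [], [], []
        for b in bundles:
            pat_rows.append({
                "patient_id": b.patient_id, "age_years": b.age_years,
                "sex": b.sex, "weight_kg": b.weight_kg, "icu_in": b.icu_in,
                "icu_out": b.icu_out,
                "death_time": np.nan if b.death_time is None else b.death_time,
            })
            obs.append(b.observations.assign(patient_id=b.patient_id))
            inf.append(b.infusions.assign(patient_id=b.patient_id))
            abx.append(pd.DataFrame({"patient_id": b.patient_id,
                                     "time_hours": np.asarray(b.antibiotics, dtype=float)}))
            cul.append(pd.DataFrame({"patient_id": b.patient_id,
                                     "time_hours": np.asarray(b.cultures, dtype=float)}))
            sofa.append(b.sofa.assign(patient_id=b.patient_id))

        def cat(frames, cols):
            frames = [f for f in frames if len(f)]
            if not frames:
                return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
            out = pd.concat(frames, ignore_index=True)
            return out[cols]

        return cls(
            patients=pd.DataFrame(pat_rows),
            observations=cat(obs, ["patient_id", "time_hours", "variable", "value"]),
            infusions=cat(inf, ["patient_id", "drug_name", "rate_value",
                                "rate_units", "weight_based", "start_hours",
                                "end_hours"]),
            antibiotics=cat(abx, ["patient_id", "time_hours"]),
            cultures=cat(cul, ["patient_id", "time_hours"]),
            sofa=cat(sofa, ["patient_id", "time_hours", "total_score"]),
        )


def _nee_rate(cls_label: int, dyn: ClassDynamics, level: float, t: np.ndarray,
              onset: float, inf_start: float, inf_end: float,
              rng: np.random.Generator) -> np.ndarray:
    """Mean NEE-equivalent norepinephrine rate at times ``t`` plus noise.

    ``level`` is the patient's own severity (class level plus a per-patient
    offset).
    """
    if cls_label == RECOVERY:
        frac = np.clip((inf_end - t) / max(inf_end - inf_start, 1e-6), 0.0, 1.0)
        mean = 0.04 + (level - 0.04) * frac
    else:
        mean = level + dyn.nee_slope * (t - onset)
    return np.maximum(0.02, mean + rng.normal(0.0, dyn.nee_sd, size=t.shape))


def generate(config: SimConfig) -> tuple[BundleSet, pd.DataFrame]:
    """Simulate ``config.n_patients`` ICU stays.

    Returns the event tables as a :class:`BundleSet` together with a
    ground-truth table (``patient_id``, ``planted_class``, ``planted_onset``,
    ``planted_eligible``, ``perturbation``) used by round-trip oracle tests.
    Deterministic for a fixed config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    eff = config.effect_params

    classes = rng.choice(3, size=n, p=np.asarray(config.class_priors, dtype=float))
    ineligible = rng.random(n) < config.ineligible_fraction
    perturb_kind = rng.integers(0, len(_PERTURBATIONS), size=n)

    age = np.round(rng.uniform(18, 95, size=n))
    age[ineligible & (perturb_kind == 0)] = rng.integers(
        15, 18, size=int((ineligible & (perturb_kind == 0)).sum()))
    sex = np.where(rng.random(n) < 0.55, "M", "F")
    weight = np.clip(np.round(rng.normal(80, 16, size=n), 1), 40.0, 160.0)

    icu_in = np.full(n, ICU_IN_HOURS)
    onset_off = _q(rng.uniform(2, 20, size=n))
    short_icu = ineligible & (perturb_kind == 2)
    onset_off[short_icu] = _q(rng.uniform(1, 3, size=int(short_icu.sum())))
    onset = icu_in + onset_off
    enroll = onset + 24.0
    wend = enroll + 48.0

    # --- sepsis-onset anchors -------------------------------------------
    # Variant A: antibiotics first (t_susp = onset, SOFA rise within +12 h);
    # variant B: SOFA rise first (t_sofa = onset, suspicion pair later).
    # Perturbed patients always use a compact variant-B layout so that their
    # onset stays recoverable and only the intended criterion is violated.
    variant_a = (rng.random(n) < 0.6) & ~ineligible
    t_sofa = np.where(variant_a, onset + _q(rng.uniform(0.0, 12.0, size=n)), onset)
    abx_t = np.where(variant_a, onset, onset + _q(rng.uniform(0.5, 20.0, size=n)))
    abx_t[ineligible] = onset[ineligible] + 0.5
    cult_gap = np.where(variant_a, _q(rng.uniform(0.5, 12.0, size=n)),
                        _q(rng.uniform(0.5, 3.0, size=n)))
    cult_t = abx_t + cult_gap
    cult_t[ineligible] = abx_t[ineligible] + 0.5
    t_sofa[ineligible] = onset[ineligible]

    # --- vasopressor episode skeleton -----------------------------------
    vaso_start = onset + _q(rng.uniform(0.5, 8.0, size=n))
    early_death = ineligible & (perturb_kind == 1)
    late_vaso = ineligible & (perturb_kind == 3)
    vaso_start[early_death] = onset[early_death] + _q(
        rng.uniform(0.5, 2.0, size=int(early_death.sum())))
    vaso_start[late_vaso] = onset[late_vaso] + _q(
        rng.uniform(26.0, 40.0, size=int(late_vaso.sum())))
    vaso_start[short_icu] = onset[short_icu] + 0.5

    death = np.full(n, np.nan)
    rapid = (classes == RAPID_DEATH) & ~ineligible
    death[rapid] = enroll[rapid] + _q(rng.uniform(1.0, 47.0, size=int(rapid.sum())))
    death[early_death] = onset[early_death] + _q(
        rng.uniform(4.0, 20.0, size=int(early_death.sum())))

    # primary-episode end; for eligible recovery this IS the planted
    # liberation time (no restart afterwards, so labels are exact)
    vaso_end = np.full(n, np.nan)
    recov = (classes == RECOVERY) & ~ineligible
    vaso_end[recov] = enroll[recov] + _q(rng.uniform(4.0, 44.0, size=int(recov.sum())))
    persist = (classes == PERSISTENT_ILL) & ~ineligible
    restart = persist & (rng.random(n) < 0.3)
    ongoing = persist & ~restart
    vaso_end[ongoing] = wend[ongoing] + _q(rng.uniform(4.0, 24.0, size=int(ongoing.sum())))
    vaso_end[restart] = enroll[restart] + _q(rng.uniform(8.0, 36.0, size=int(restart.sum())))
    restart_start = np.full(n, np.nan)
    restart_end = np.full(n, np.nan)
    restart_start[restart] = vaso_end[restart] + _q(
        rng.uniform(1.5, 12.0, size=int(restart.sum())))
    # the restart must still be running at the end of the outcome window,
    # otherwise the patient genuinely recovers under the labeling rules
    restart_end[restart] = wend[restart] + _q(
        rng.uniform(4.0, 24.0, size=int(restart.sum())))
    vaso_end[rapid] = death[rapid]
    vaso_end[early_death] = death[early_death]
    vaso_end[late_vaso] = vaso_start[late_vaso] + _q(
        rng.uniform(24.0, 48.0, size=int(late_vaso.sum())))

    icu_out = np.where(
        np.isfinite(death), death,
        np.maximum(wend, np.where(np.isnan(restart_end),
                                  np.where(np.isnan(vaso_end), wend, vaso_end),
                                  restart_end))
        + _q(rng.uniform(6.0, 48.0, size=n)))
    icu_out[short_icu] = icu_in[short_icu] + _q(
        rng.uniform(10.0, 20.0, size=int(short_icu.sum())))
    vaso_end[short_icu] = icu_out[short_icu]
    vaso_end = np.minimum(vaso_end, icu_out)

    pids = np.array([f"P{i:05d}" for i in range(n)])
    nee_patient_level = np.array([
        max(0.06, eff[int(c)].nee_level + o) for c, o in
        zip(classes, rng.normal(0.0, NEE_BETWEEN_PATIENT_SD, size=n))])

    # --- per-patient small tables (infusions, antibiotics, cultures, SOFA)
    inf_pid, inf_drug, inf_rate, inf_units, inf_wb, inf_s, inf_e = \
        [], [], [], [], [], [], []
    sofa_pid, sofa_t, sofa_v = [], [], []
    secondary_drugs = np.array(["vasopressin", "dopamine", "phenylephrine",
                                "epinephrine"])

    def add_segments(i, drug, s, e, rates, units, wb):
        k = len(s)
        inf_pid.append(np.repeat(pids[i], k))
        inf_drug.append(np.repeat(drug, k))
        inf_rate.append(np.round(rates, 4))
        inf_units.append(np.repeat(units, k))
        inf_wb.append(np.repeat(wb, k))
        inf_s.append(_q(s))
        inf_e.append(_q(e))

    for i in range(n):
        dyn = eff[int(classes[i])]
        s0, e0 = float(vaso_start[i]), float(vaso_end[i])
        if np.isfinite(e0) and e0 > s0:
            bounds = _q(np.arange(s0, e0, 4.0))
            seg_s = bounds
            seg_e = np.append(bounds[1:], e0)
            keep = seg_e > seg_s
            seg_s, seg_e = seg_s[keep], seg_e[keep]
            mid = 0.5 * (seg_s + seg_e)
            rates = _nee_rate(int(classes[i]), dyn, nee_patient_level[i],
                              mid, float(onset[i]), s0, e0, rng)
            if rng.random() < 0.2:  # some sites chart absolute μg/min rates
                add_segments(i, "norepinephrine", seg_s, seg_e,
                             rates * weight[i], "ug/min", False)
            else:
                add_segments(i, "norepinephrine", seg_s, seg_e, rates,
                             "ug/kg/min", True)
            if rng.random() < 0.25:  # secondary agent inside the episode
                drug = str(rng.choice(secondary_drugs))
                s2 = _q(s0 + rng.uniform(0.0, 4.0))
                e2 = _q(min(e0, s2 + rng.uniform(6.0, 24.0)))
                if e2 > s2:
                    if drug == "vasopressin":
                        add_segments(i, drug, np.array([s2]), np.array([e2]),
                                     np.array([rng.uniform(0.01, 0.03)]),
                                     "U/min", False)
                    else:
                        lo, hi = {"dopamine": (3.0, 8.0),
                                  "phenylephrine": (0.5, 1.5),
                                  "epinephrine": (0.02, 0.08)}[drug]
                        add_segments(i, drug, np.array([s2]), np.array([e2]),
                                     np.array([rng.uniform(lo, hi)]),
                                     "ug/kg/min", True)
            if recov[i] and rng.random() < 0.15 and e0 + 2.0 < icu_out[i]:
                # a zero-rate charting artefact after liberation; must not
                # affect episodes or NEE
                add_segments(i, "norepinephrine", _q(np.array([e0 + 0.5])),
                             _q(np.array([e0 + 2.0])), np.array([0.0]),
                             "ug/kg/min", True)
        if np.isfinite(restart_start[i]):
            rs, re = float(restart_start[i]), float(min(restart_end[i], icu_out[i]))
            if re > rs:
                mid = np.array([0.5 * (rs + re)])
                rates = _nee_rate(int(classes[i]), dyn, nee_patient_level[i],
                                  mid, float(onset[i]), rs, re, rng)
                add_segments(i, "norepinephrine", np.array([rs]), np.array([re]),
                             rates, "ug/kg/min", True)

        # SOFA series: constant baseline 2, step to 5 at the planted rise time
        end_i = min(icu_out[i], icu_in[i] + config.horizon_hours)
        grid = np.arange(icu_in[i], end_i, 6.0)
        ts = float(_q(t_sofa[i]))
        times = np.append(grid, ts) if ts <= end_i else grid
        times = _q(np.sort(times, kind="stable"))
        vals = np.where(times < ts, 2, 5).astype(int)
        sofa_pid.append(np.repeat(pids[i], len(times)))
        sofa_t.append(times)
        sofa_v.append(vals)

    infusions = pd.DataFrame({
        "patient_id": np.concatenate(inf_pid) if inf_pid else np.array([], dtype=str),
        "drug_name": np.concatenate(inf_drug) if inf_drug else np.array([], dtype=str),
        "rate_value": np.concatenate(inf_rate) if inf_rate else np.array([]),
        "rate_units": np.concatenate(inf_units) if inf_units else np.array([], dtype=str),
        "weight_based": np.concatenate(inf_wb) if inf_wb else np.array([], dtype=bool),
        "start_hours": np.concatenate(inf_s) if inf_s else np.array([]),
        "end_hours": np.concatenate(inf_e) if inf_e else np.array([]),
    })
    sofa = pd.DataFrame({
        "patient_id": np.concatenate(sofa_pid),
        "time_hours": np.concatenate(sofa_t),
        "total_score": np.concatenate(sofa_v),
    })
    antibiotics = pd.DataFrame({"patient_id": pids, "time_hours": _q(abx_t)})
    cultures = pd.DataFrame({"patient_id": pids, "time_hours": _q(cult_t)})

    observations = _generate_observations(
        config, rng, pids, classes, onset, icu_in, icu_out, eff)

    patients = pd.DataFrame({
        "patient_id": pids, "age_years": age, "sex": sex,
        "weight_kg": weight, "icu_in": icu_in, "icu_out": _q(icu_out),
        "death_time": _q(death),
    })
    truth = pd.DataFrame({
        "patient_id": pids,
        "planted_class": classes.astype(int),
        "planted_onset": _q(onset),
        "planted_eligible": ~ineligible,
        "perturbation": np.where(
            ineligible, np.array(_PERTURBATIONS)[perturb_kind], ""),
    })
    bundles = BundleSet(patients=patients, observations=observations,
                        infusions=infusions, antibiotics=antibiotics,
                        cultures=cultures, sofa=sofa)
    return bundles, truth


def _grid(rng, icu_in, obs_end, interval, offset, n):
    """Vectorised jittered per-patient sampling grids; returns (pid_idx, t)."""
    span = np.maximum(0.0, obs_end - icu_in - offset)
    cnt = np.floor(span / interval - 1e-9).astype(int) + 1
    cnt[span <= 0] = 0
    total = int(cnt.sum())
    pid_idx = np.repeat(np.arange(n), cnt)
    starts = np.cumsum(cnt) - cnt
    k = np.arange(total) - np.repeat(starts, cnt)
    t = icu_in[pid_idx] + offset + k * interval + rng.uniform(-0.15, 0.15, size=total)
    t = _q(np.clip(t, icu_in[pid_idx], obs_end[pid_idx] - 1e-3))
    return pid_idx, t


def _generate_observations(config, rng, pids, classes, onset, icu_in, icu_out, eff):
    n = len(pids)
    obs_end = np.minimum(icu_out, icu_in + config.horizon_hours)

    lvl = {name: np.array([getattr(eff[c], name) for c in classes])
           for name in ("hr_level", "sbp_level", "lactate_level", "urine_rate")}
    sd = {name: np.array([getattr(eff[c], name) for c in classes])
          for name in ("hr_sd", "sbp_sd", "lactate_sd", "urine_sd")}
    # between-patient heterogeneity: the spread that keeps class separation
    # realistic (no variable is a clean oracle at the patient level)
    lvl["hr_level"] = lvl["hr_level"] + rng.normal(0, 12.0, n)
    lvl["sbp_level"] = lvl["sbp_level"] + rng.normal(0, 12.0, n)
    lvl["lactate_level"] = np.maximum(0.5, lvl["lactate_level"] + rng.normal(0, 1.0, n))
    lvl["urine_rate"] = np.maximum(0.0, lvl["urine_rate"] + rng.normal(0, 25.0, n))
    base = {
        "heart_rate": rng.normal(84, 8, n), "sbp": rng.normal(122, 10, n),
        "resp_rate": rng.normal(17, 2, n), "spo2": rng.normal(97, 1, n),
        "temperature": rng.normal(36.8, 0.3, n), "urine_output": rng.normal(70, 20, n),
    }
    post = {"resp_rate": {0: 22.0, 1: 19.5, 2: 18.5},
            "spo2": {0: 94.0, 1: 95.8, 2: 96.2},
            "temperature": {0: 37.4, 1: 37.15, 2: 37.0},
            "gcs": {0: 11.0, 1: 13.2, 2: 13.8}}
    post_off = {"resp_rate": rng.normal(0, 2.5, n),
                "spo2": rng.normal(0, 1.2, n),
                "temperature": rng.normal(0, 0.3, n),
                "gcs": rng.normal(0, 1.2, n)}

    var_codes, values, all_pid, all_t = [], [], [], []
    var_names: list[str] = []

    def emit(name, pid_idx, t, vals):
        keep = rng.random(len(vals)) >= config.missingness_rate
        var_names.append(name)
        code = len(var_names) - 1
        var_codes.append(np.full(int(keep.sum()), code, dtype=np.int16))
        values.append(np.round(vals[keep], 3))
        all_pid.append(pid_idx[keep].astype(np.int32))
        all_t.append(t[keep])

    pid_idx, t = _grid(rng, icu_in, obs_end, config.obs_interval_hours, 0.25, n)
    after = t >= onset[pid_idx]
    m = len(t)

    hr = np.where(after, lvl["hr_level"][pid_idx], base["heart_rate"][pid_idx]) \
        + rng.normal(0, 1, m) * sd["hr_sd"][pid_idx]
    emit("heart_rate", pid_idx, t, np.clip(hr, 20, 220))
    sbp = np.where(after, lvl["sbp_level"][pid_idx], base["sbp"][pid_idx]) \
        + rng.normal(0, 1, m) * sd["sbp_sd"][pid_idx]
    sbp = np.clip(sbp, 40, 250)
    emit("sbp", pid_idx, t, sbp)
    dbp = np.clip(0.6 * sbp + rng.normal(0, 6, m), 20, 160)
    emit("dbp", pid_idx, t, dbp)
    emit("map", pid_idx, t, np.clip((sbp + 2 * dbp) / 3 + rng.normal(0, 3, m), 25, 180))
    for name, sdv in (("resp_rate", 3.0), ("spo2", 2.0), ("temperature", 0.4)):
        pc = np.array([post[name][c] for c in classes]) + post_off[name]
        v = np.where(after, pc[pid_idx], base[name][pid_idx]) + rng.normal(0, sdv, m)
        lo, hi = {"resp_rate": (4, 70), "spo2": (50, 100),
                  "temperature": (33, 42.5)}[name]
        emit(name, pid_idx, t, np.clip(v, lo, hi))
    gcs_pc = np.array([post["gcs"][c] for c in classes]) + post_off["gcs"]
    gcs = np.where(after, gcs_pc[pid_idx], 15.0) + rng.normal(0, 1.5, m)
    emit("gcs", pid_idx, t, np.clip(np.round(gcs), 3, 15))
    uo = np.where(after, lvl["urine_rate"][pid_idx], base["urine_output"][pid_idx]) \
        + rng.normal(0, 1, m) * sd["urine_sd"][pid_idx]
    emit("urine_output", pid_idx, t, np.maximum(0.0, uo))

    lab_idx, lab_t = _grid(rng, icu_in, obs_end, config.lab_interval_hours, 0.5, n)
    ml = len(lab_t)
    lab_after = lab_t >= onset[lab_idx]
    lac = np.where(lab_after, lvl["lactate_level"][lab_idx],
                   np.maximum(0.4, rng.normal(1.3, 0.3, n))[lab_idx]) \
        + rng.normal(0, 1, ml) * sd["lactate_sd"][lab_idx]
    emit("lactate", lab_idx, lab_t, np.clip(lac, 0.2, 25))
    for name, (mean, bsd, wsd, lo, hi) in LAB_BASELINES.items():
        pat = rng.normal(mean, bsd, n)
        v = pat[lab_idx] + rng.normal(0, wsd, ml)
        emit(name, lab_idx, lab_t, np.clip(v, lo, hi))

    pid_cat = pd.Categorical.from_codes(np.concatenate(all_pid), categories=pids)
    var_cat = pd.Categorical.from_codes(
        np.concatenate(var_codes).astype(int), categories=var_names)
    return pd.DataFrame({
        "patient_id": pid_cat,
        "time_hours": np.concatenate(all_t),
        "variable": var_cat,
        "value": np.concatenate(values),
    })
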