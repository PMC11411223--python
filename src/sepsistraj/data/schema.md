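# Event-table schema

One file per table kind (CSV or Parquet). Time columns are ISO-8601
timestamps at millisecond precision; in memory they become real-valued hours
since the fixed epoch 2021-01-01T00:00:00.

## patients
| column | type | meaning |
|---|---|---|
| patient_id | str | opaque identifier |
| age_years | float | age at admission |
| sex | str | "M" / "F" |
| weight_kg | float | admission weight |
| icu_in / icu_out | timestamp | ICU admission / discharge |
| death_time | timestamp or empty | time of death if died |

## observations
`patient_id, timestamp, variable, value` — long-format vital-sign and
laboratory measurements. Variable names and units are listed in
`registry.yaml` (`timevarying_features`).

## infusions
`patient_id, drug_name, rate_value, rate_units, weight_based, start_timestamp,
end_timestamp` — vasopressor infusion segments. `rate_units` is `ug/kg/min`
(weight_based true), `ug/min` (absolute; divided by weight on use), or
`U/min` (vasopressin). Zero-rate rows are charting artefacts and are ignored
by episode logic.

## antibiotics / cultures
`patient_id, timestamp` — IV antibiotic administrations and culture
specimen acquisitions.

## sofa
`patient_id, timestamp, total_score` — SOFA total score series (0–24).

## ground_truth (simulation only)
`patient_id, planted_class, planted_onset[, planted_eligible, perturbation]`
— the simulator's oracle: planted trajectory class (0 rapid death,
1 persistent ill, 2 recovery) and planted sepsis-onset time.
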