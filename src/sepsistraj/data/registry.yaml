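# Default feature registry.
#
# static_features:      name -> source column (patients table or derived)
# timevarying_features: name -> {variable, units}; each contributes
#                       max/min/median/cv summaries over the 24-h window
#                       between sepsis identification and enrollment.
# window_total_features: variables additionally summarised as a window total
#                       (urine output is clinically a cumulative volume).
# outlier_ranges:       physiologic-plausibility bounds (closed interval);
#                       raw observations outside the bounds are discarded
#                       before summarisation.
# nee_conversion:       drug -> factor to norepinephrine-equivalent
#                       μg/kg/min (vasopressin factor applies to U/min).

static_features:
  age_years: age_years
  sex_male: sex
  weight_kg: weight_kg
  onset_from_admission_hours: derived

timevarying_features:
  nee: {variable: nee, units: ug/kg/min}
  heart_rate: {variable: heart_rate, units: bpm}
  sbp: {variable: sbp, units: mmHg}
  dbp: {variable: dbp, units: mmHg}
  map: {variable: map, units: mmHg}
  resp_rate: {variable: resp_rate, units: breaths/min}
  spo2: {variable: spo2, units: "%"}
  temperature: {variable: temperature, units: degC}
  gcs: {variable: gcs, units: points}
  urine_output: {variable: urine_output, units: mL/h}
  lactate: {variable: lactate, units: mmol/L}
  creatinine: {variable: creatinine, units: mg/dL}
  bun: {variable: bun, units: mg/dL}
  wbc: {variable: wbc, units: 10^9/L}
  hemoglobin: {variable: hemoglobin, units: g/dL}
  hematocrit: {variable: hematocrit, units: "%"}
  platelets: {variable: platelets, units: 10^9/L}
  sodium: {variable: sodium, units: mmol/L}
  potassium: {variable: potassium, units: mmol/L}
  chloride: {variable: chloride, units: mmol/L}
  bicarbonate: {variable: bicarbonate, units: mmol/L}
  glucose: {variable: glucose, units: mg/dL}
  bilirubin: {variable: bilirubin, units: mg/dL}
  albumin: {variable: albumin, units: g/dL}
  arterial_ph: {variable: arterial_ph, units: pH}
  pao2: {variable: pao2, units: mmHg}
  paco2: {variable: paco2, units: mmHg}
  aptt: {variable: aptt, units: s}
  pt_inr: {variable: pt_inr, units: ratio}
  calcium: {variable: calcium, units: mg/dL}
  magnesium: {variable: magnesium, units: mg/dL}
  phosphate: {variable: phosphate, units: mg/dL}
  alt: {variable: alt, units: U/L}
  ast: {variable: ast, units: U/L}
  troponin: {variable: troponin, units: ng/mL}

window_total_features: [urine_output]

outlier_ranges:
  heart_rate: [10, 300]
  sbp: [20, 300]
  dbp: [5, 250]
  map: [10, 250]
  resp_rate: [0, 80]
  spo2: [0, 100]
  temperature: [25, 45]
  gcs: [3, 15]
  urine_output: [0, 2000]
  lactate: [0, 40]
  creatinine: [0, 30]
  bun: [0, 250]
  wbc: [0, 300]
  hemoglobin: [1, 25]
  hematocrit: [5, 75]
  platelets: [0, 2000]
  sodium: [90, 185]
  potassium: [1, 12]
  chloride: [60, 150]
  bicarbonate: [0, 60]
  glucose: [10, 2000]
  bilirubin: [0, 80]
  albumin: [0.3, 8]
  arterial_ph: [6.5, 8]
  pao2: [10, 700]
  paco2: [5, 200]
  aptt: [10, 300]
  pt_inr: [0.3, 25]
  calcium: [2, 20]
  magnesium: [0.3, 10]
  phosphate: [0.2, 20]
  alt: [0, 10000]
  ast: [0, 10000]
  troponin: [0, 100]
  nee: [0, 10]

nee_conversion:
  norepinephrine: 1.0
  epinephrine: 1.0
  phenylephrine: 0.1
  dopamine: 0.01
  vasopressin: 2.5
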