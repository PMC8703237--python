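# Default dichotomization rules for the 20 clinical variables.
#
# Each phenotype is TRUE when ALL of its conditions hold, FALSE when at least
# one fails, and missing when any required input is missing. Comparators:
# ge / le are boundary-inclusive, gt / lt strict, band means low <= x < high,
# flag passes a 0/1 column through. Thresholds may be sex-specific
# ({male:, female:}); 'egfr' and 'ldl_chol' are composed variables computed
# from raw inputs before these rules are applied.
version: 1
phenotypes:
  - name: low_egfr
    units: mL/min/1.73m2
    conditions:
      - {source: egfr, comparator: le, threshold: 60}
  - name: high_triglycerides
    units: mmol/L
    conditions:
      - {source: triglycerides, comparator: ge, threshold: 2.3}
  - name: high_ldl_chol
    units: mmol/L
    conditions:
      - {source: ldl_chol, comparator: ge, threshold: 4.1}
  - name: high_total_chol
    units: mmol/L
    conditions:
      - {source: total_chol, comparator: ge, threshold: 6.2}
  - name: low_hdl_chol
    units: mmol/L
    conditions:
      - {source: hdl_chol, comparator: le, threshold: 1.3}
  - name: diabetes
    conditions:
      - {source: diabetes, comparator: flag}
  - name: metabolic_syndrome
    conditions:
      - {source: metabolic_syndrome, comparator: flag}
  - name: sex
    conditions:
      - {source: sex, comparator: flag}   # TRUE = male
  - name: lipid_medication
    conditions:
      - {source: lipid_medication, comparator: flag}
  - name: low_age
    units: years
    conditions:
      - {source: age, comparator: lt, threshold: 45}
  - name: middle_age
    units: years
    conditions:
      - {source: age, comparator: band, threshold: {low: 45, high: 65}}
  - name: high_age
    units: years
    conditions:
      - {source: age, comparator: ge, threshold: 65}
  - name: high_hscrp
    units: mg/L
    conditions:
      - {source: hscrp, comparator: gt, threshold: 3}
  - name: blood_pressure_lowering_medication
    conditions:
      - {source: blood_pressure_lowering_medication, comparator: flag}
  - name: obesity
    units: kg/m2, cm
    conditions:
      - {source: bmi, comparator: ge, threshold: 30}
      - {source: waist, comparator: ge, threshold: {male: 102, female: 93}}
  - name: low_hemoglobin
    units: mmol/L
    conditions:
      - {source: hgb, comparator: le, threshold: {male: 6.67, female: 7.62}}
  - name: low_wbc
    units: 1e9/L
    conditions:
      - {source: wbc, comparator: le, threshold: 4.5}
  - name: current_smoking
    conditions:
      - {source: current_smoking, comparator: flag}
  - name: alcohol_consumption
    conditions:
      - {source: alcohol_consumption, comparator: flag}
  - name: high_pressure
    units: mmHg
    conditions:
      - {source: sbp, comparator: ge, threshold: 140}
      - {source: dbp, comparator: ge, threshold: 90}
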